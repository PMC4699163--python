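"""Framed message transports: in-process loopback and length-prefixed TCP.

Every protocol message is (1-byte type, payload).  The TCP framing is a
1-byte type followed by an 8-byte big-endian payload length.  The loopback
transport moves the same frames through thread-safe queues so a whole session
can run in one process (the simulate mode used by tests and the CLI).
"""

from __future__ import annotations

import queue
import socket
import struct


class TransportError(RuntimeError):
    pass


class LoopbackTransport:
    def __init__(self, inbox: queue.Queue, outbox: queue.Queue, timeout: float = 120.0):
        self._in = inbox
        self._out = outbox
        self.timeout = timeout

    def send(self, msg_type: int, payload: bytes) -> None:
        self._out.put((msg_type, payload))

    def recv(self) -> tuple[int, bytes]:
        try:
            return self._in.get(timeout=self.timeout)
        except queue.Empty:
            raise TransportError("peer did not respond (timeout)") from None

    def close(self) -> None:
        pass


def loopback_pair(timeout: float = 120.0) -> tuple[LoopbackTransport, LoopbackTransport]:
    q_ab: queue.Queue = queue.Queue()
    q_ba: queue.Queue = queue.Queue()
    return (
        LoopbackTransport(q_ba, q_ab, timeout),
        LoopbackTransport(q_ab, q_ba, timeout),
    )


class TcpTransport:
    HEADER = struct.Struct(">BQ")

    def __init__(self, sock: socket.socket):
        self._sock = sock

    @classmethod
    def connect(cls, host: str, port: int, timeout: float = 120.0) -> "TcpTransport":
        try:
            sock = socket.create_connection((host, port), timeout=timeout)
        except OSError as e:
            raise TransportError(f"cannot reach peer {host}:{port}: {e}") from e
        return cls(sock)

    @classmethod
    def listen_once(cls, host: str, port: int, timeout: float = 120.0) -> "TcpTransport":
        srv = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
        srv.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
        srv.bind((host, port))
        srv.listen(1)
        srv.settimeout(timeout)
        try:
            conn, _ = srv.accept()
        except OSError as e:
            raise TransportError(f"no peer connected on {host}:{port}: {e}") from e
        finally:
            srv.close()
        conn.settimeout(timeout)
        return cls(conn)

    def send(self, msg_type: int, payload: bytes) -> None:
        try:
            self._sock.sendall(self.HEADER.pack(msg_type, len(payload)) + payload)
        except OSError as e:
            raise TransportError(f"send failed: {e}") from e

    def recv(self) -> tuple[int, bytes]:
        header = self._recv_exact(self.HEADER.size)
        msg_type, length = self.HEADER.unpack(header)
        return msg_type, self._recv_exact(length)

    def _recv_exact(self, n: int) -> bytes:
        buf = bytearray()
        while len(buf) < n:
            try:
                chunk = self._sock.recv(n - len(buf))
            except OSError as e:
                raise TransportError(f"recv failed: {e}") from e
            if not chunk:
                raise TransportError("connection closed mid-message")
            buf += chunk
        return bytes(buf)

    def close(self) -> None:
        try:
            self._sock.close()
        except OSError:
            pass
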