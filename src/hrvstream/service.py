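"""JSON REST/WebSocket service for HRV records.

Endpoints (all token-authenticated, all JSON):

* ``GET  /all``                          -- every stored record, id order
* ``GET  /latest``                       -- the most recent record (404 when empty)
* ``GET  /data_by_time?start=&end=``     -- records in a closed ISO-8601 interval
* ``GET  /download_hrv_json``            -- bulk download of the full store
* ``POST /receive_hrv_data``             -- submit a record (server assigns the id)
* ``GET  /ws``                           -- WebSocket push of every stored record
* ``GET  /stream``                       -- newline-delimited JSON push (same feed)

The API key travels in an ``Authorization: Bearer <key>`` or ``X-API-Key``
header.  Storage is an in-process append-only log with strictly increasing
record ids and optional JSON-lines file persistence.  The server is the
stdlib ``ThreadingHTTPServer``; the WebSocket endpoint implements the
server side of the RFC 6455 framing directly (handshake + unfragmented
text frames), which is all a push feed needs.
"""

from __future__ import annotations

import base64
import hashlib
import json
import struct
import threading
import time
from dataclasses import dataclass, field
from datetime import datetime
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from queue import Empty, SimpleQueue
from typing import Callable, Iterable, Iterator
from urllib.parse import parse_qs, urlparse

from pydantic import ValidationError

from .records import HRVPayload, HRVRecord, iso_utc, parse_iso

_WS_GUID = "258EAFA5-E914-47DA-95CA-C5AB0DC85B11"


@dataclass(frozen=True)
class ApiConfig:
    api_key: str
    update_period_s: float = 5.0
    host: str = "127.0.0.1"
    port: int = 0  # 0 = ephemeral

    def __post_init__(self) -> None:
        if not self.api_key:
            raise ValueError("api_key must be non-empty")
        if self.update_period_s <= 0:
            raise ValueError("update_period_s must be positive")


class HRVStore:
    """Thread-safe append-only record log with push subscriptions."""

    def __init__(self, persist_path: str | Path | None = None) -> None:
        self._records: list[HRVRecord] = []
        self._lock = threading.Lock()
        self._subscribers: list[SimpleQueue] = []
        self._persist_path = Path(persist_path) if persist_path else None
        if self._persist_path and self._persist_path.exists():
            for line in self._persist_path.read_text().splitlines():
                if line.strip():
                    self._records.append(HRVRecord.model_validate_json(line))

    def __len__(self) -> int:
        with self._lock:
            return len(self._records)

    @property
    def next_record_id(self) -> int:
        with self._lock:
            return self._records[-1].record_id + 1 if self._records else 0

    def append(self, record: HRVRecord) -> HRVRecord:
        """Append a fully formed record; id must exceed the newest stored one."""
        with self._lock:
            if self._records and record.record_id <= self._records[-1].record_id:
                raise ValueError("record_id must be strictly increasing")
            self._records.append(record)
            subs = list(self._subscribers)
            if self._persist_path:
                with open(self._persist_path, "a") as fh:
                    fh.write(record.model_dump_json() + "\n")
        for q in subs:
            q.put(record)
        return record

    def submit(self, payload: HRVPayload, timestamp: str | None = None) -> HRVRecord:
        """Assign an id (and timestamp if missing) and store the payload."""
        with self._lock:
            rid = self._records[-1].record_id + 1 if self._records else 0
        ts = payload.timestamp or timestamp or iso_utc(datetime.now().astimezone())
        record = HRVRecord(record_id=rid, timestamp=ts, **payload.model_dump(exclude={"timestamp"}))
        return self.append(record)

    def all(self) -> list[HRVRecord]:
        with self._lock:
            return list(self._records)

    def latest(self) -> HRVRecord | None:
        with self._lock:
            return self._records[-1] if self._records else None

    def by_time(self, start: datetime, end: datetime) -> list[HRVRecord]:
        """Records with start <= timestamp <= end (closed interval), id order."""
        with self._lock:
            return [r for r in self._records if start <= r.time <= end]

    def subscribe(self, backlog: bool = True) -> SimpleQueue:
        """Register a push subscriber; optionally pre-load existing records."""
        q: SimpleQueue = SimpleQueue()
        with self._lock:
            if backlog:
                for r in self._records:
                    q.put(r)
            self._subscribers.append(q)
        return q

    def unsubscribe(self, q: SimpleQueue) -> None:
        with self._lock:
            if q in self._subscribers:
                self._subscribers.remove(q)

    def close_subscribers(self) -> None:
        with self._lock:
            subs = list(self._subscribers)
        for q in subs:
            q.put(None)


def publisher_loop(
    records: Iterable[HRVRecord],
    store: HRVStore,
    update_period_s: float | None = None,
    sleep: Callable[[float], None] = time.sleep,
) -> int:
    """Feed a record source into the store, optionally paced in real time.

    With ``update_period_s`` set, emission is paced at that cadence (one
    record per period); with ``None`` the source is drained as fast as it
    produces (replay mode).  On source exhaustion the final record has
    already been flushed to the store and subscribers are told to wind
    down.  Returns the number of records published.
    """
    n = 0
    try:
        for rec in records:
            store.append(rec)
            n += 1
            if update_period_s:
                sleep(update_period_s)
    finally:
        store.close_subscribers()
    return n


# ---------------------------------------------------------------------------
# HTTP layer


def _ws_accept(key: str) -> str:
    digest = hashlib.sha1((key + _WS_GUID).encode()).digest()
    return base64.b64encode(digest).decode()


def _ws_text_frame(payload: bytes) -> bytes:
    header = bytearray([0x81])  # FIN + text opcode
    n = len(payload)
    if n < 126:
        header.append(n)
    elif n < 1 << 16:
        header.append(126)
        header += struct.pack(">H", n)
    else:
        header.append(127)
        header += struct.pack(">Q", n)
    return bytes(header) + payload


class _Handler(BaseHTTPRequestHandler):
    protocol_version = "HTTP/1.1"
    server: "HRVHTTPServer"

    # -- plumbing ----------------------------------------------------------

    def log_message(self, fmt: str, *args) -> None:  # quiet by default
        if self.server.verbose:
            super().log_message(fmt, *args)

    def _send_json(self, status: int, obj: object, download: bool = False) -> None:
        body = json.dumps(obj).encode()
        self.send_response(status)
        self.send_header("Content-Type", "application/json")
        if download:
            self.send_header("Content-Disposition", 'attachment; filename="hrv_data.json"')
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def _authenticated(self) -> bool:
        auth = self.headers.get("Authorization", "")
        if auth.startswith("Bearer ") and auth[7:] == self.server.config.api_key:
            return True
        return self.headers.get("X-API-Key") == self.server.config.api_key

    def _reject_auth(self) -> None:
        self._send_json(401, {"detail": "invalid or missing API key"})

    # -- routes ------------------------------------------------------------

    def do_GET(self) -> None:  # noqa: N802 (stdlib casing)
        url = urlparse(self.path)
        if not self._authenticated():
            self._reject_auth()
            return
        store = self.server.store
        if url.path == "/all":
            self._send_json(200, [r.to_json_dict() for r in store.all()])
        elif url.path == "/latest":
            rec = store.latest()
            if rec is None:
                self._send_json(404, {"detail": "no records stored"})
            else:
                self._send_json(200, rec.to_json_dict())
        elif url.path == "/data_by_time":
            self._data_by_time(url.query)
        elif url.path == "/download_hrv_json":
            self._send_json(200, [r.to_json_dict() for r in store.all()], download=True)
        elif url.path == "/ws":
            self._websocket()
        elif url.path == "/stream":
            self._ndjson_stream()
        else:
            self._send_json(404, {"detail": f"unknown path {url.path}"})

    def do_POST(self) -> None:  # noqa: N802
        url = urlparse(self.path)
        if not self._authenticated():
            self._reject_auth()
            return
        if url.path != "/receive_hrv_data":
            self._send_json(404, {"detail": f"unknown path {url.path}"})
            return
        length = int(self.headers.get("Content-Length", 0))
        body = self.rfile.read(length)
        try:
            payload = HRVPayload.model_validate_json(body)
        except ValidationError as exc:
            self._send_json(422, {"detail": json.loads(exc.json(include_url=False))})
            return
        record = self.server.store.submit(payload)
        self._send_json(201, record.to_json_dict())

    def _data_by_time(self, query: str) -> None:
        params = parse_qs(query)
        try:
            start_raw = params["start"][0]
            end_raw = params["end"][0]
        except KeyError:
            self._send_json(422, {"detail": "start and end query parameters are required"})
            return
        try:
            start, end = parse_iso(start_raw), parse_iso(end_raw)
        except ValueError:
            self._send_json(422, {"detail": "start/end must be ISO-8601 timestamps"})
            return
        if start > end:
            self._send_json(422, {"detail": "start must not exceed end"})
            return
        self._send_json(200, [r.to_json_dict() for r in self.server.store.by_time(start, end)])

    # -- push feeds --------------------------------------------------------

    def _drain_subscription(self) -> Iterator[bytes]:
        q = self.server.store.subscribe(backlog=True)
        try:
            while True:
                try:
                    rec = q.get(timeout=0.5)
                except Empty:
                    if self.server.shutting_down.is_set():
                        return
                    continue
                if rec is None:  # publisher wind-down sentinel
                    return
                yield rec.model_dump_json().encode()
        finally:
            self.server.store.unsubscribe(q)

    def _websocket(self) -> None:
        key = self.headers.get("Sec-WebSocket-Key")
        if self.headers.get("Upgrade", "").lower() != "websocket" or not key:
            self._send_json(400, {"detail": "expected a WebSocket upgrade request"})
            return
        self.send_response_only(101)
        self.send_header("Upgrade", "websocket")
        self.send_header("Connection", "Upgrade")
        self.send_header("Sec-WebSocket-Accept", _ws_accept(key))
        self.end_headers()
        self.close_connection = True
        try:
            for body in self._drain_subscription():
                self.wfile.write(_ws_text_frame(body))
                self.wfile.flush()
            self.wfile.write(bytes([0x88, 0x00]))  # close frame
        except (BrokenPipeError, ConnectionResetError):
            pass

    def _ndjson_stream(self) -> None:
        self.send_response(200)
        self.send_header("Content-Type", "application/x-ndjson")
        self.end_headers()
        self.close_connection = True
        try:
            for body in self._drain_subscription():
                self.wfile.write(body + b"\n")
                self.wfile.flush()
        except (BrokenPipeError, ConnectionResetError):
            pass


class HRVHTTPServer(ThreadingHTTPServer):
    daemon_threads = True
    allow_reuse_address = True

    def __init__(self, config: ApiConfig, store: HRVStore, verbose: bool = False):
        self.config = config
        self.store = store
        self.verbose = verbose
        self.shutting_down = threading.Event()
        super().__init__((config.host, config.port), _Handler)


@dataclass
class HRVService:
    """A running service: store + HTTP server on a background thread."""

    config: ApiConfig
    store: HRVStore = field(default_factory=HRVStore)
    verbose: bool = False

    def __post_init__(self) -> None:
        self._server = HRVHTTPServer(self.config, self.store, self.verbose)
        self._thread: threading.Thread | None = None

    @property
    def address(self) -> tuple[str, int]:
        return self._server.server_address[:2]

    @property
    def base_url(self) -> str:
        host, port = self.address
        return f"http://{host}:{port}"

    def start(self) -> "HRVService":
        self._thread = threading.Thread(target=self._server.serve_forever, daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._server.shutting_down.set()
        self.store.close_subscribers()
        self._server.shutdown()
        self._server.server_close()
        if self._thread:
            self._thread.join(timeout=5)
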