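"""REST/WebSocket service contract: auth, endpoints, push streaming, cadence."""

import base64
import hashlib
import json
import socket
import threading
import time
from http.client import HTTPConnection

import pytest

from hrvstream import (
    ApiConfig,
    HRVPayload,
    HRVRecord,
    HRVService,
    HRVStore,
    publisher_loop,
    rr_to_samples,
    stream_records,
)

KEY = "test-key-123"


@pytest.fixture
def service():
    svc = HRVService(ApiConfig(api_key=KEY)).start()
    yield svc
    svc.stop()


def request(svc, method, path, body=None, key=KEY, header="bearer"):
    host, port = svc.address
    conn = HTTPConnection(host, port, timeout=5)
    headers = {}
    if key is not None:
        if header == "bearer":
            headers["Authorization"] = f"Bearer {key}"
        else:
            headers["X-API-Key"] = key
    if body is not None:
        body = json.dumps(body)
        headers["Content-Type"] = "application/json"
    conn.request(method, path, body=body, headers=headers)
    resp = conn.getresponse()
    data = resp.read()
    conn.close()
    return resp.status, json.loads(data) if data else None


def store_some(svc, n=3):
    for i in range(n):
        svc.store.append(
            HRVRecord(record_id=i, timestamp=f"2026-01-01T00:00:{i:02d}Z",
                      hr=70.0 + i, rmssd=40.0, sdnn=50.0, pnn50=10.0,
                      lf_hf=1.2, n_nn=60)
        )


class TestAuth:
    @pytest.mark.parametrize("method, path", [
        ("GET", "/all"), ("GET", "/latest"),
        ("GET", "/data_by_time?start=2026-01-01T00:00:00Z&end=2026-01-02T00:00:00Z"),
        ("GET", "/download_hrv_json"), ("POST", "/receive_hrv_data"),
    ])
    def test_every_endpoint_requires_a_token(self, service, method, path):
        body = {"n_nn": 10} if method == "POST" else None
        assert request(service, method, path, body, key=None)[0] == 401
        assert request(service, method, path, body, key="wrong")[0] == 401
        assert len(service.store) == 0  # failed auth never mutates

    def test_x_api_key_header_accepted(self, service):
        status, body = request(service, "GET", "/all", header="x-api-key")
        assert status == 200 and body == []


class TestEndpoints:
    def test_all_empty_store(self, service):
        assert request(service, "GET", "/all") == (200, [])

    def test_all_returns_insertion_order(self, service):
        store_some(service)
        status, body = request(service, "GET", "/all")
        assert status == 200
        assert [r["record_id"] for r in body] == [0, 1, 2]

    def test_latest(self, service):
        assert request(service, "GET", "/latest")[0] == 404
        store_some(service, 5)
        status, body = request(service, "GET", "/latest")
        assert status == 200 and body["record_id"] == 4

    def test_data_by_time_closed_interval(self, service):
        store_some(service, 3)  # records at 00:00:00, :01, :02
        q = "/data_by_time?start=2026-01-01T00:00:01Z&end=2026-01-01T00:00:01Z"
        status, body = request(service, "GET", q)
        assert status == 200
        assert [r["record_id"] for r in body] == [1]

    def test_data_by_time_full_span_equals_all(self, service):
        store_some(service)
        q = "/data_by_time?start=2020-01-01T00:00:00Z&end=2030-01-01T00:00:00Z"
        assert request(service, "GET", q)[1] == request(service, "GET", "/all")[1]

    def test_data_by_time_empty_window(self, service):
        store_some(service)
        q = "/data_by_time?start=2027-01-01T00:00:00Z&end=2027-01-02T00:00:00Z"
        assert request(service, "GET", q) == (200, [])

    @pytest.mark.parametrize("q", [
        "/data_by_time",
        "/data_by_time?start=garbage&end=2026-01-01T00:00:00Z",
        "/data_by_time?start=2026-01-02T00:00:00Z&end=2026-01-01T00:00:00Z",
    ])
    def test_data_by_time_validation(self, service, q):
        assert request(service, "GET", q)[0] == 422

    def test_download_round_trips_to_all(self, service):
        store_some(service)
        assert request(service, "GET", "/download_hrv_json")[1] == \
            request(service, "GET", "/all")[1]

    def test_receive_then_latest(self, service):
        payload = {"hr": 72.0, "rmssd": 35.5, "sdnn": 48.0, "pnn50": 12.0,
                   "lf_hf": 1.8, "n_nn": 64, "timestamp": "2026-02-01T10:00:00Z"}
        status, body = request(service, "POST", "/receive_hrv_data", payload)
        assert status == 201
        status, latest = request(service, "GET", "/latest")
        assert latest["rmssd"] == 35.5 and latest["record_id"] == body["record_id"]

    def test_receive_rejects_negative_rmssd_with_field_reason(self, service):
        status, body = request(service, "POST", "/receive_hrv_data",
                               {"rmssd": -3.0, "n_nn": 20})
        assert status == 422
        assert any("rmssd" in str(item.get("loc")) for item in body["detail"])
        assert len(service.store) == 0

    def test_json_round_trip_identity(self, service):
        store_some(service)
        _, body = request(service, "GET", "/all")
        parsed = [HRVRecord.model_validate(r) for r in body]
        assert parsed == service.store.all()


class TestStoreInvariants:
    def test_record_ids_strictly_increase(self):
        store = HRVStore()
        store.submit(HRVPayload(n_nn=10))
        store.submit(HRVPayload(n_nn=12))
        ids = [r.record_id for r in store.all()]
        assert ids == sorted(ids) and len(set(ids)) == len(ids)
        with pytest.raises(ValueError):
            store.append(HRVRecord(record_id=0, timestamp="2026-01-01T00:00:00Z", n_nn=1))

    def test_jsonl_persistence_round_trip(self, tmp_path):
        path = tmp_path / "records.jsonl"
        store = HRVStore(persist_path=path)
        store.submit(HRVPayload(n_nn=10, hr=70.0))
        store.submit(HRVPayload(n_nn=11, hr=71.0))
        reloaded = HRVStore(persist_path=path)
        assert reloaded.all() == store.all()


class TestPublisherAndStreams:
    def test_sixty_second_replay_yields_twelve_records(self):
        store = HRVStore()
        samples = rr_to_samples([1000.0] * 60)
        n = publisher_loop(stream_records(samples), store)
        assert abs(n - 12) <= 1
        assert len(store) == n

    def test_gated_metrics_serialized_as_nulls_cadence_unbroken(self):
        store = HRVStore()
        # 2500-ms intervals are implausible: every window cleans to 0 NN,
        # so every metric gates, yet records keep flowing at the cadence
        samples = rr_to_samples([2500.0] * 24)  # 60 s of beat time
        publisher_loop(stream_records(samples), store)
        assert len(store) >= 11
        assert all(r.n_nn == 0 for r in store.all())
        assert all(r.hr is None and r.rmssd is None for r in store.all())

    def test_subscribers_receive_every_record_in_order(self):
        store = HRVStore()
        q = store.subscribe(backlog=True)
        samples = rr_to_samples([800.0] * 75)
        publisher_loop(stream_records(samples), store)
        got = []
        while True:
            rec = q.get(timeout=1)
            if rec is None:
                break
            got.append(rec)
        assert got == store.all()

    def test_websocket_client_receives_stored_records_in_order(self, service):
        store_some(service, 2)
        host, port = service.address
        sock = socket.create_connection((host, port), timeout=5)
        ws_key = base64.b64encode(b"0123456789abcdef").decode()
        handshake = (
            f"GET /ws HTTP/1.1\r\nHost: {host}:{port}\r\n"
            f"Authorization: Bearer {KEY}\r\n"
            "Upgrade: websocket\r\nConnection: Upgrade\r\n"
            f"Sec-WebSocket-Key: {ws_key}\r\nSec-WebSocket-Version: 13\r\n\r\n"
        )
        sock.sendall(handshake.encode())
        buf = b""
        while b"\r\n\r\n" not in buf:
            buf += sock.recv(4096)
        headers, _, buf = buf.partition(b"\r\n\r\n")
        assert b"101" in headers.splitlines()[0]
        expected_accept = base64.b64encode(
            hashlib.sha1((ws_key + "258EAFA5-E914-47DA-95CA-C5AB0DC85B11").encode()).digest()
        ).decode()
        assert expected_accept.encode() in headers

        # two more records arrive while connected
        def publish_more():
            time.sleep(0.2)
            for i in (2, 3):
                service.store.append(HRVRecord(
                    record_id=i, timestamp=f"2026-01-01T00:00:{i:02d}Z",
                    hr=70.0 + i, n_nn=60))
            service.store.close_subscribers()

        t = threading.Thread(target=publish_more)
        t.start()
        frames = []
        data = buf
        while True:
            while len(data) < 2:
                chunk = sock.recv(4096)
                if not chunk:
                    break
                data += chunk
            if len(data) < 2:
                break
            opcode = data[0] & 0x0F
            length = data[1] & 0x7F
            offset = 2
            if length == 126:
                length = int.from_bytes(data[2:4], "big")
                offset = 4
            while len(data) < offset + length:
                data += sock.recv(4096)
            payload, data = data[offset:offset + length], data[offset + length:]
            if opcode == 0x8:  # close
                break
            frames.append(json.loads(payload))
        t.join()
        sock.close()
        assert [f["record_id"] for f in frames] == [0, 1, 2, 3]
        assert [f["hr"] for f in frames] == [70.0, 71.0, 72.0, 73.0]

    def test_ws_requires_auth(self, service):
        host, port = service.address
        conn = HTTPConnection(host, port, timeout=5)
        conn.request("GET", "/ws", headers={"Upgrade": "websocket"})
        assert conn.getresponse().status == 401
        conn.close()
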