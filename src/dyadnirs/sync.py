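"""Two-site start-trigger handshake with event logging.

A third machine runs a handshake server; each laboratory's client
connects, and once the server has received connections from all expected
clients it broadcasts a start trigger to every one of them, then closes
the connections (no in-task messaging).  Each client logs wall-clock
times for six event classes — code run, connection made, trigger
received, experiment start, start of each task/rest block, experiment
end — so that per-event lags between the sites' computer clocks can be
audited against an independently measured ground-truth clock offset.

Wire format (one ASCII line per message over a TCP stream):

    client -> server:  ``HELLO <site_id>``
    server -> client:  ``START <unix_time>``

Log file format, one record per line:

    ``ISO8601<TAB>site_id<TAB>event<TAB>detail``
"""

from __future__ import annotations

import socket
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

EVENT_ORDER = (
    "code_run",
    "connected",
    "trigger_received",
    "experiment_start",
    "block_start",
    "experiment_end",
)


@dataclass
class LogRecord:
    site_id: str
    event: str
    wall_clock: float  # seconds since epoch, microsecond precision
    detail: str = ""

    def to_line(self) -> str:
        iso = datetime.fromtimestamp(self.wall_clock, tz=timezone.utc).isoformat()
        return f"{iso}\t{self.site_id}\t{self.event}\t{self.detail}"

    @classmethod
    def from_line(cls, line: str) -> "LogRecord":
        iso, site, event, detail = line.rstrip("\n").split("\t", 3)
        t = datetime.fromisoformat(iso).timestamp()
        return cls(site_id=site, event=event, wall_clock=t, detail=detail)


@dataclass
class SyncLog:
    site_id: str
    records: list = field(default_factory=list)

    def add(self, event: str, wall_clock: float, detail: str = "") -> LogRecord:
        rec = LogRecord(self.site_id, event, round(wall_clock, 6), detail)
        self.records.append(rec)
        return rec

    def events(self, event: str) -> list:
        return [r for r in self.records if r.event == event]

    @property
    def completed(self) -> bool:
        have = {r.event for r in self.records}
        return all(e in have for e in EVENT_ORDER)

    def write(self, path) -> None:
        with open(path, "a") as fh:  # append-only by contract
            for rec in self.records:
                fh.write(rec.to_line() + "\n")

    @classmethod
    def read(cls, path, site_id: str | None = None) -> "SyncLog":
        records = []
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    records.append(LogRecord.from_line(line))
        sid = site_id if site_id is not None else (records[0].site_id if records else "")
        return cls(site_id=sid, records=records)


@dataclass
class HostResult:
    triggered: bool
    trigger_time: float | None
    client_sites: list
    log: SyncLog


def run_host(
    port: int,
    n_clients: int = 2,
    timeout: float = 10.0,
    host: str = "127.0.0.1",
    log_path=None,
    clock=time.time,
) -> HostResult:
    """Accept ``n_clients`` connections, then broadcast the start trigger.

    If fewer than ``n_clients`` connect within ``timeout`` seconds the
    session aborts and no trigger is sent to anyone.  Connections are
    closed immediately after the trigger.  Returns the broadcast record
    and the server-side log.
    """
    log = SyncLog(site_id="server")
    log.add("code_run", clock())
    server = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
    server.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
    conns: list = []
    sites: list = []
    try:
        server.bind((host, port))
        server.listen(n_clients)
        deadline = time.monotonic() + timeout
        while len(conns) < n_clients:
            remaining = deadline - time.monotonic()
            if remaining <= 0:
                log.add("abort", clock(), f"timeout with {len(conns)}/{n_clients} clients")
                if log_path:
                    log.write(log_path)
                return HostResult(False, None, sites, log)
            server.settimeout(remaining)
            try:
                conn, _ = server.accept()
            except socket.timeout:
                continue
            conn.settimeout(max(remaining, 0.1))
            hello = conn.makefile("r").readline().strip()
            site = hello.split(" ", 1)[1] if hello.startswith("HELLO ") else "?"
            conns.append(conn)
            sites.append(site)
            log.add("connected", clock(), site)
        t0 = clock()
        msg = f"START {t0:.6f}\n".encode()
        for conn in conns:
            conn.sendall(msg)
        log.add("trigger_sent", t0, f"{n_clients} clients")
        return HostResult(True, t0, sites, log)
    finally:
        for conn in conns:
            conn.close()
        server.close()
        if log_path:
            log.write(log_path)


def run_client(
    host: str,
    port: int,
    site_id: str,
    paradigm=None,
    paradigm_hook=None,
    timeout: float = 10.0,
    retries: int = 5,
    backoff: float = 0.05,
    clock=time.time,
    sleep=time.sleep,
    log_path=None,
) -> SyncLog:
    """Connect to the handshake server, block for the trigger, run the paradigm.

    Connection attempts follow an exponential-backoff retry policy.  After
    the trigger, each block of ``paradigm`` is logged (``block_start``)
    and ``paradigm_hook(block)`` invoked; ``sleep`` (injectable for
    testing) waits out the block durations.  If no trigger arrives within
    ``timeout`` the experiment never starts and the partial log carries an
    ``abort`` record.
    """
    log = SyncLog(site_id=site_id)
    log.add("code_run", clock())
    sock = None
    last_err: Exception | None = None
    for attempt in range(retries):
        try:
            sock = socket.create_connection((host, port), timeout=timeout)
            break
        except OSError as err:
            last_err = err
            time.sleep(backoff * (2**attempt))
    if sock is None:
        log.add("abort", clock(), f"connection failed: {last_err}")
        if log_path:
            log.write(log_path)
        raise ConnectionError(f"could not reach host after {retries} attempts") from last_err
    try:
        sock.sendall(f"HELLO {site_id}\n".encode())
        log.add("connected", clock())
        sock.settimeout(timeout)
        try:
            line = sock.makefile("r").readline()
        except socket.timeout:
            line = ""
        if not line.startswith("START"):
            log.add("abort", clock(), "no trigger received")
            if log_path:
                log.write(log_path)
            return log
        log.add("trigger_received", clock(), line.strip())
    finally:
        sock.close()  # connection closes once the paradigm begins

    log.add("experiment_start", clock())
    if paradigm is not None:
        start = clock()
        for blk in paradigm.blocks:
            target = blk.onset - (clock() - start)
            if target > 0:
                sleep(target)
            log.add("block_start", clock(), f"{blk.condition}:{blk.duration:g}s")
            if paradigm_hook is not None:
                paradigm_hook(blk)
        remaining = paradigm.run_length - (clock() - start)
        if remaining > 0:
            sleep(remaining)
    log.add("experiment_end", clock())
    if log_path:
        log.write(log_path)
    return log


def estimate_offset(
    log_a: SyncLog,
    log_b: SyncLog,
    ground_truth_offset: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-event clock lags between two site logs.

    Events of the same class are matched by occurrence order; for each
    matched pair the lag is ``(t_a - t_b) - ground_truth_offset`` (the
    known clock difference between the two computers is subtracted so
    residual lags reflect delivery/processing delay only).  Unmatched
    events are reported with NaN lag, not dropped.  Returns the per-event
    frame and a mean/SD/max summary over the matched lags.
    """
    rows = []
    events = list(dict.fromkeys([r.event for r in log_a.records + log_b.records]))
    for event in events:
        ea, eb = log_a.events(event), log_b.events(event)
        for i in range(max(len(ea), len(eb))):
            ta = ea[i].wall_clock if i < len(ea) else np.nan
            tb = eb[i].wall_clock if i < len(eb) else np.nan
            rows.append(
                {"event": event, "occurrence": i, "t_a": ta, "t_b": tb,
                 "lag": (ta - tb) - ground_truth_offset}
            )
    frame = pd.DataFrame(rows)
    lags = frame["lag"].dropna()
    summary = {
        "n_matched": int(lags.size),
        "n_unmatched": int(frame["lag"].isna().sum()),
        "mean_lag": float(lags.mean()) if lags.size else np.nan,
        "sd_lag": float(lags.std(ddof=0)) if lags.size else np.nan,
        "max_abs_lag": float(lags.abs().max()) if lags.size else np.nan,
    }
    return frame, summary
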