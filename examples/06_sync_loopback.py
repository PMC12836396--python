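"""Two-site start-trigger handshake over loopback.

A handshake server waits for both laboratory clients, broadcasts the
start trigger, and each client logs the six event classes while running
its paradigm; the offset estimator then audits the two logs.
"""

import socket
import threading
import time

from dyadnirs import generate_paradigm, run_client, run_host
from dyadnirs.sync import estimate_offset

s = socket.socket()
s.bind(("127.0.0.1", 0))
port = s.getsockname()[1]
s.close()

paradigm = generate_paradigm(["live"], n_repeats=1)
host_result, logs = {}, {}

host = threading.Thread(
    target=lambda: host_result.update(r=run_host(port, n_clients=2, timeout=5.0))
)
host.start()
time.sleep(0.05)
clients = [
    threading.Thread(
        target=lambda site=site: logs.update(
            {site: run_client("127.0.0.1", port, site, paradigm=paradigm,
                              sleep=lambda _t: None)}  # no real-time waits here
        )
    )
    for site in ("UK", "US")
]
for t in clients:
    t.start()
for t in clients:
    t.join()
host.join()

print(f"trigger broadcast at {host_result['r'].trigger_time:.6f} "
      f"to {host_result['r'].client_sites}")
for site, log in logs.items():
    print(f"{site}: {len(log.records)} events logged, complete={log.completed}")
frame, summary = estimate_offset(logs["UK"], logs["US"], ground_truth_offset=0.0)
print(f"per-event clock lag: mean {summary['mean_lag'] * 1e3:.3f} ms, "
      f"max |lag| {summary['max_abs_lag'] * 1e3:.3f} ms over "
      f"{summary['n_matched']} matched events")
# on loopback both clients receive the trigger within a fraction of a
# millisecond; across real sites the ground-truth clock offset is
# subtracted before judging lags
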