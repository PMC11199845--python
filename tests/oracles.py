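"""Independent brute-force reference implementations used only by tests.

Everything here recomputes indicators from raw samples with plain loops,
deliberately sharing no code with the package's event-based path.
"""

import math


def wall_distance(x, y, W, H):
    return min(x, W - x, y, H - y)


def brute_force_wf(times, xy, sl, W, H, testing_time_s,
                   resting_thr=0.2, belt_sl=0.5, min_sl=2.0):
    """Per-sample classification of the six wall-following indicators."""
    n = len(times)
    speed = [float("nan")] * n
    for i in range(1, n):
        d = math.hypot(xy[i][0] - xy[i - 1][0], xy[i][1] - xy[i - 1][1])
        speed[i] = d / (times[i] - times[i - 1])
    if n > 1:
        speed[0] = speed[1]
    resting = [s < resting_thr if not math.isnan(s) else False for s in speed]
    member = [wall_distance(p[0], p[1], W, H) <= belt_sl * sl for p in xy]

    events = []  # (start, end, path)
    i = 0
    while i < n:
        if member[i]:
            j = i
            path = 0.0
            while j + 1 < n and member[j + 1]:
                path += math.hypot(xy[j + 1][0] - xy[j][0],
                                   xy[j + 1][1] - xy[j][1])
                j += 1
            if j > i and path >= min_sl * sl:
                events.append((i, j, path))
            i = j + 1
        else:
            i += 1

    dist = sum(e[2] for e in events)
    dur = sum(times[e[1]] - times[e[0]] for e in events)
    mobile = 0.0
    for i0, j0, _ in events:
        for i in range(i0 + 1, j0 + 1):
            if not resting[i]:
                mobile += times[i] - times[i - 1]
    rest_time = 0.0
    for i in range(1, n):
        if resting[i]:
            rest_time += times[i] - times[i - 1]
    finite = [s for s in speed if not math.isnan(s)]
    return {
        "wf_distance_sl": dist / sl,
        "wf_frequency": len(events),
        "wf_time_pct": 100.0 * dur / testing_time_s,
        "wf_resting_time_s": rest_time,
        "wf_speed_sl_s": dist / mobile / sl if mobile > 0 else 0.0,
        "wf_max_speed_sl_s": (max(finite) / sl) if finite else 0.0,
    }


def brute_force_stim(times, xy, sl, cx, cy, half_len, half_wid,
                     testing_time_s, resting_thr=0.2):
    """Per-sample classification of the four stimulation-range indicators."""
    n = len(times)
    speed = [float("nan")] * n
    for i in range(1, n):
        d = math.hypot(xy[i][0] - xy[i - 1][0], xy[i][1] - xy[i - 1][1])
        speed[i] = d / (times[i] - times[i - 1])
    if n > 1:
        speed[0] = speed[1]
    resting = [s < resting_thr if not math.isnan(s) else False for s in speed]
    member = [abs(p[0] - cx) <= half_len and abs(p[1] - cy) <= half_wid
              for p in xy]
    freq = 0
    prev = False
    for m in member:
        if m and not prev:
            freq += 1
        prev = m
    time_in = 0.0
    sp_sum = 0.0
    mob_t = 0.0
    mx = 0.0
    for i in range(1, n):
        dt = times[i] - times[i - 1]
        if member[i]:
            time_in += dt
            mx = max(mx, speed[i])
            if not resting[i]:
                sp_sum += speed[i] * dt
                mob_t += dt
    return {
        "s_frequency": freq,
        "s_time_pct": 100.0 * time_in / testing_time_s,
        "s_speed_sl_s": sp_sum / mob_t / sl if mob_t > 0 else 0.0,
        "s_max_speed_sl_s": mx / sl,
    }


def segment_circle_distance_numeric(p, heading, sl, cx, cy, r, k=20001):
    """Dense sampling of body points: min distance to the circle boundary."""
    ux, uy = math.cos(heading), math.sin(heading)
    best = float("inf")
    for i in range(k):
        s = -0.5 * sl + sl * i / (k - 1)
        bx, by = p[0] + s * ux, p[1] + s * uy
        best = min(best, math.hypot(bx - cx, by - cy) - r)
    return max(0.0, best) / sl
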