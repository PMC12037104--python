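"""Independent from-scratch oracles used to cross-check streaming code.

The detector oracles recompute every statistic at every index from prefix
arrays (numpy cumulative sums) instead of carrying incremental state, and
re-derive the episode structure by rerunning on the post-reset suffix; they
share no code with the streaming implementations they check.
"""

from __future__ import annotations

import numpy as np


def ddm_oracle(errors, min_instances=30, warning_sigma=2.0, drift_sigma=3.0):
    """All (index, level) DDM events for a stream, recomputed from scratch."""
    errors = np.asarray(errors, dtype=float)
    events: list[tuple[int, str]] = []
    offset = 0
    while offset < len(errors):
        seg = errors[offset:]
        i = np.arange(1, len(seg) + 1, dtype=float)
        p = np.cumsum(seg) / i
        s = np.sqrt(p * (1.0 - p) / i)
        ps = p + s
        p_min = s_min = np.inf
        in_warn = False
        episode_warned = False
        drift_at = None
        for k in range(min_instances - 1, len(seg)):
            if ps[k] < p_min + s_min:
                p_min, s_min = p[k], s[k]
            if ps[k] > p_min + drift_sigma * s_min:
                if not episode_warned:
                    events.append((offset + k, "warning"))
                events.append((offset + k, "drift"))
                drift_at = k
                break
            if ps[k] > p_min + warning_sigma * s_min:
                if not in_warn:
                    events.append((offset + k, "warning"))
                    in_warn = True
                    episode_warned = True
            else:
                in_warn = False
        if drift_at is None:
            break
        offset += drift_at + 1
    return events


def eddm_oracle(errors, min_errors=30, alpha=0.95, beta=0.90):
    """All (index, level) EDDM events, recomputed from error positions."""
    errors = np.asarray(errors, dtype=int)
    events: list[tuple[int, str]] = []
    offset = 0
    while offset < len(errors):
        positions = np.flatnonzero(errors[offset:]) + offset
        if len(positions) < 2:
            break
        distances = np.diff(positions).astype(float)
        k = np.arange(1, len(distances) + 1, dtype=float)
        mean = np.cumsum(distances) / k
        # population sd from scratch (two-pass style via cumulative squares)
        sq = np.cumsum(distances**2) / k
        sd = np.sqrt(np.maximum(sq - mean**2, 0.0))
        level = mean + 2.0 * sd
        p_max = s_max = -np.inf
        in_warn = False
        episode_warned = False
        drift_at = None
        for j in range(len(distances)):
            idx = int(positions[j + 1])
            if level[j] > p_max + 2.0 * s_max:
                p_max, s_max = mean[j], sd[j]
                in_warn = False
                continue
            if j + 1 < min_errors:
                continue
            ratio = level[j] / (p_max + 2.0 * s_max)
            if ratio < beta:
                if not episode_warned:
                    events.append((idx, "warning"))
                events.append((idx, "drift"))
                drift_at = idx
                break
            if ratio < alpha:
                if not in_warn:
                    events.append((idx, "warning"))
                    in_warn = True
                    episode_warned = True
            else:
                in_warn = False
        if drift_at is None:
            break
        offset = drift_at + 1
    return events


def scale_oracle(values, method, power_exponent=0.5):
    """Entry-by-entry recomputation of a scaling fitted on ``values`` itself."""
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        mean = col.mean()
        sd = col.std(ddof=1)
        span = col.max() - col.min()
        for i, x in enumerate(col):
            if method == "none":
                y = x
            elif method == "centering":
                y = x - mean
            elif method == "autoscaling":
                y = (x - mean) / sd if sd > 0 else x - mean
            elif method == "pareto":
                y = (x - mean) / np.sqrt(sd) if sd > 0 else x - mean
            elif method == "range":
                y = (x - mean) / span if span > 0 else x - mean
            elif method == "vast":
                y = (x - mean) / sd * (mean / sd) if sd > 0 else x - mean
            elif method == "level":
                y = (x - mean) / mean if mean != 0 else x - mean
            elif method == "log10":
                y = np.log10(x)
            elif method == "power":
                y = x**power_exponent
            else:
                raise ValueError(method)
            out[i, j] = y
    return out


def outlier_oracle(values, groups):
    """Per-entry recomputation of the 2-sd outlier rule."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    flags = np.zeros_like(values, dtype=bool)
    for g in np.unique(groups):
        rows = np.flatnonzero(groups == g)
        for j in range(values.shape[1]):
            col = values[rows, j]
            mean = col.mean()
            sd = col.std(ddof=1)
            for r in rows:
                flags[r, j] = abs(values[r, j] - mean) > 2.0 * sd
    return flags
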