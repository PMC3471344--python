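"""Numba event-loop kernel for the fractionation simulator.

Kept separate so the simulator module stays readable; everything here is an
implementation detail.  The kernel mutates the g/h presence arrays and the
per-position event log in place and records one row per deletion event.

Event-type codes: 0=A, 1=B, 2=C, 3=D, 4=E, 5=other (>=3 runs merged).
"""

import numpy as np
from numba import njit

TYPE_A, TYPE_B, TYPE_C, TYPE_D, TYPE_E, TYPE_OTHER = 0, 1, 2, 3, 4, 5


@njit(cache=True)
def run_until(
    g,
    h,
    ev_id,
    ev_chr,
    dup_count,
    next_eid,
    theta_target,
    phi,
    mu,
    gen,
    rec_theta,
    rec_type,
    rec_chrom,
    rec_drawn,
    rec_deleted,
    rec_skipped,
    rec_blocked,
    rec_clipped,
):
    """Apply deletion events until theta <= theta_target or saturation.

    Draw order per event is fixed (chromosome, anchor, length) for
    reproducibility.  The anchor is uniform over positions still present on
    both homeologs (rejection sampling).  Returns (dup_count, next_eid,
    n_recorded).
    """
    n = g.shape[0]
    cap = rec_theta.shape[0]
    count = 0
    use_geom = mu > 1.0
    log_s = np.log(1.0 - 1.0 / mu) if use_geom else 0.0

    while dup_count > 0 and float(dup_count) / n > theta_target and count < cap:
        # chromosome: 1 = G with probability phi, else 2 = H
        c = 1 if gen.random() < phi else 2
        # anchor: uniform over {i : g[i] = h[i] = 1}
        while True:
            i = int(gen.integers(0, n))
            if g[i] == 1 and h[i] == 1:
                break
        # deletion length a ~ geometric(1/mu) on {1, 2, ...}
        if use_geom:
            u = gen.random()
            a = 1 + int(np.log1p(-u) / log_s)
        else:
            a = 1

        mine = g if c == 1 else h
        other = h if c == 1 else g

        eid = next_eid
        pos = i
        converted = 0
        skipped = 0
        blocked = 0
        last_conv = i
        while converted < a and pos < n:
            if mine[pos] == 0:
                # skippable collision: previously excised on this homeolog
                pos += 1
                skipped += 1
                continue
            if other[pos] == 0:
                # blocking collision: other copy already lost
                blocked = 1
                break
            mine[pos] = 0
            ev_id[pos] = eid
            ev_chr[pos] = c
            dup_count -= 1
            converted += 1
            last_conv = pos
            pos += 1
        clipped = 1 if (converted < a and blocked == 0) else 0

        # classify by the pre-existing single-copy runs absorbed into the
        # consolidated run now containing this event
        left = i
        while left > 0 and g[left - 1] + h[left - 1] == 1:
            left -= 1
        right = last_conv
        while right < n - 1 and g[right + 1] + h[right + 1] == 1:
            right += 1
        nblocks = 0
        has_left = 0
        prev_pre = False
        for q in range(left, right + 1):
            pre = ev_id[q] != eid
            if pre and not prev_pre:
                nblocks += 1
                if q < i:
                    has_left = 1
            prev_pre = pre
        if nblocks == 0:
            etype = TYPE_A
        elif nblocks == 1:
            etype = TYPE_B if has_left == 1 else TYPE_C
        elif nblocks == 2:
            etype = TYPE_E if has_left == 1 else TYPE_D
        else:
            etype = TYPE_OTHER

        rec_theta[count] = float(dup_count) / n
        rec_type[count] = etype
        rec_chrom[count] = c
        rec_drawn[count] = a
        rec_deleted[count] = converted
        rec_skipped[count] = skipped
        rec_blocked[count] = blocked
        rec_clipped[count] = clipped
        count += 1
        next_eid += 1

    return dup_count, next_eid, count
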