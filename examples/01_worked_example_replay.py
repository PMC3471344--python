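"""Replay the five-event skip/block worked example and read off (l, r).

Two homeologous chromosomes G and H start identical over 16 genes
(labeled -7..8).  Five scripted deletion events — with one skippable
collision (a previously excised segment on the same homeolog is invisible
to the machinery) and one blocking collision (the other homeolog's copy is
already gone, so deletion must stop) — leave two consolidated runs of
single-copy genes.
"""

from fractorun import replay, table1_pair
from fractorun.fixtures import TABLE1_OFFSET

pair, script = table1_pair()
pair, events, runs, stats = replay(pair, script)

for ev in events:
    where = [p - TABLE1_OFFSET for p in ev.deleted_positions]
    note = "blocked" if ev.blocked else ("%d skipped" % ev.skipped_count
                                         if ev.skipped_count else "clean")
    print(f"event {ev.event_id}: chr{ev.chromosome} a={ev.drawn_length} "
          f"deleted {where} ({note})")

print()
for r in runs:
    lo = r.start - TABLE1_OFFSET
    print(f"single-copy run {lo}..{lo + r.length - 1}: length={r.length} "
          f"r={r.event_count} both_homeologs={r.both_chromosomes}")
print(f"\ntheta = {stats.theta:.4f} (proportion of genes still duplicated)")

# The run at -5..1 was built by 3 events (one from G, two from H: a blocked
# deletion and a single-gene loss); the run at 4..7 by 2 events on G with a
# skip.  Neither r is observable from the final sequences alone - that is
# exactly why pi(r) needs a model.
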