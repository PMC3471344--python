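"""Worked-example fixture and scenario files.

``TABLE1_SCRIPT`` is the five-event deletion script of the worked skip/block
example: a 16-gene interval labeled -7..8, on which the five events produce
two consolidated single-copy runs, one of length 7 built from 3 events
(with content from both homeologs, the last event blocked), and one of
length 4 built from 2 events (G only, with one skip).
"""

from __future__ import annotations

import json
from pathlib import Path

from .core import GenomePair

__all__ = [
    "TABLE1_OFFSET",
    "TABLE1_LENGTH",
    "TABLE1_SCRIPT",
    "table1_pair",
    "script_to_dict",
    "load_script",
    "generate_fixtures",
]

# worked-example labels -7..8 map to 0-based indices via +TABLE1_OFFSET
TABLE1_OFFSET = 7
TABLE1_LENGTH = 16

# (chromosome, anchor in -7..8 labels, drawn length a); chromosome 1 = G, 2 = H
TABLE1_SCRIPT: tuple[tuple[int, int, int], ...] = (
    (1, -1, 3),
    (2, -4, 1),
    (1, 5, 1),
    (1, 4, 3),
    (2, -5, 4),
)


def table1_pair() -> tuple[GenomePair, list[tuple[int, int, int]]]:
    """Fresh all-duplicate pair and the five-event script in 0-based indices."""
    pair = GenomePair.identical(TABLE1_LENGTH)
    script = [(c, a + TABLE1_OFFSET, ln) for c, a, ln in TABLE1_SCRIPT]
    return pair, script


def script_to_dict() -> dict:
    return {
        "offset": TABLE1_OFFSET,
        "length": TABLE1_LENGTH,
        "events": [
            {"chromosome": "G" if c == 1 else "H", "anchor": a, "a": ln}
            for c, a, ln in TABLE1_SCRIPT
        ],
    }


def load_script(path) -> tuple[GenomePair, list[tuple[int, int, int]]]:
    """Read an event-script JSON file; returns (fresh pair, 0-based script)."""
    with open(path) as fh:
        doc = json.load(fh)
    offset = int(doc.get("offset", 0))
    length = int(doc["length"])
    pair = GenomePair.identical(length)
    script = []
    for ev in doc["events"]:
        chrom = 1 if ev["chromosome"] == "G" else 2
        script.append((chrom, int(ev["anchor"]) + offset, int(ev["a"])))
    return pair, script


_SCENARIOS = (
    {"name": "unbiased_small_deletions", "mu": 2.0, "phi": 0.5, "seed": 101},
    {"name": "unbiased_large_deletions", "mu": 11.0, "phi": 0.5, "seed": 102},
    {"name": "biased_large_deletions", "mu": 11.0, "phi": 1.0, "seed": 103},
)


def generate_fixtures(outdir) -> list[Path]:
    """Write table1.json and three scenario files; byte-identical across runs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    p = outdir / "table1.json"
    with open(p, "w") as fh:
        json.dump(script_to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    written.append(p)

    for sc in _SCENARIOS:
        doc = {
            "name": sc["name"],
            "mu": sc["mu"],
            "phi": sc["phi"],
            "length": 100_000,
            "stop_theta": 0.1,
            "replicates": 100,
            "seed": sc["seed"],
        }
        p = outdir / f"scenario_{sc['name']}.json"
        with open(p, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
        written.append(p)
    return written
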