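"""Bundled motif resources: the CoRNR-box human-proteome scan table.

The CoRNR box is the nuclear-receptor co-repressor motif
``L[^P]{2}[HI]I[^P]{2}[IAV][IL]``; a proteome-wide scan with this pattern
yields 67 instances in 65 human proteins (two proteins carry two instances
each).  The table ships with the package as the worked example for motif
scanning and per-motif score averaging.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .regions import CORNR_BOX_PATTERN

#: known transcription artifact in the source table: this printed motif
#: string does not match the pattern that generated the scan
CORNR_KNOWN_ARTIFACTS = frozenset({("Q562E7", "LSDITYYVY")})


def load_cornr_scan() -> pd.DataFrame:
    """The CoRNR-box scan table: accession, motif, ELM true-positive flag."""
    path = resources.files("pepbind.data") / "cornr_scan.tsv"
    with resources.as_file(path) as p:
        frame = pd.read_csv(p, sep="\t", comment="#")
    return frame


__all__ = ["CORNR_BOX_PATTERN", "CORNR_KNOWN_ARTIFACTS", "load_cornr_scan"]
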