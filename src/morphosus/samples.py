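"""Published sample accounting for the Cypriot *Sus scrofa* dental study.

These tables record how many second (M/2) and third (M/3) lower molars were
digitized per modern population and per archaeological site in the study
this package re-implements analytically.  The raw landmark data are not
deposited anywhere, so the counts serve two purposes here: bookkeeping
checks, and realistic per-group sample sizes for the synthetic scenarios.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["modern_samples", "archaeological_samples"]

_MODERN = [
    # origin, taxon, n_m2, n_m3
    ("Corsica", "Domestic pig", 32, 18),
    ("Corsica", "Wild boar", 19, 5),
    ("Corsica", "Wild crossed", 7, 3),
    ("Sardinia", "Wild boar", 9, 9),
    ("Syria", "Wild boar", 3, 1),
    ("Turkey", "Wild boar", 10, 6),
    ("Northern Africa", "Wild boar", 6, 5),
]

_ARCHAEOLOGICAL = [
    # site, period, code, n_m2, n_m3
    ("Hallan Cemi", "PPNA", "HLC", 4, 8),
    ("Cayonu", "PPNA", "CAY-PPNA", 5, 8),
    ("Gobekli", "PPNA", "GOB", 1, 1),
    ("Ain Ghazal", "PPNB", "AGT", 2, 1),
    ("Cayonu", "PPNB", "CAY-PPNB", 20, 17),
    ("Nevali Cori", "PPNB", "NVC", 4, 5),
    ("Tell Halula", "PPNB", "HAL", 9, 6),
    ("Gurcutepe", "PPNB", "GUR", 1, 1),
    ("Domuztepe", "PN", "DOM", 2, 8),
    ("Cayonu", "PN", "CAY-PN", 4, 4),
    ("Araguina", "Middle Neolithic", "COR-ARA", 2, 0),
    ("Terrina IV", "Late Neolithic", "COR-TER", 5, 5),
    ("Klimonas", "PPNA", "KLI", 33, 26),
    ("Shillourokambos middle A", "PPNB", "SHI-A", 25, 12),
    ("Shillourokambos middle B", "PPNB", "SHI-B", 2, 5),
]


def modern_samples() -> pd.DataFrame:
    """Modern wild and domestic *Sus scrofa* dental samples by origin and
    taxon, with M/2 and M/3 specimen counts (86 M/2 in total; the Corsican
    plus Sardinian hunted wild boars contribute 28 M/2)."""
    return pd.DataFrame(_MODERN, columns=["origin", "taxon", "n_m2", "n_m3"])


def archaeological_samples() -> pd.DataFrame:
    """Archaeological *Sus scrofa* dental samples by site, period and group
    code (119 M/2 in total, dominated by the Cypriot PPN sites Klimonas and
    Shillourokambos)."""
    return pd.DataFrame(_ARCHAEOLOGICAL, columns=["site", "period", "code", "n_m2", "n_m3"])
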