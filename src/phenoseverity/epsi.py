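"""E-PSI: the proportional phenotype severity index.

For each of the five severity measures, a phenotype's *proportion* is its
value divided by the maximum of that measure over all phenotypes in the
table, so the phenotype attaining the maximum gets proportion exactly 1.
E-PSI is the mean of the five proportions, hence a value in [0, 1]:

    E-PSI(x) = (1/5) * [ cost(x)/max(cost) + time(x)/max(time)
                         + com(x)/max(com) + med(x)/max(med)
                         + proc(x)/max(proc) ]

If a measure is identically zero across the table its proportion is defined
as 0 for every phenotype (zero-max guard for degenerate inputs).  Setting
``divide_by_n=False`` returns the raw sum of proportions in [0, 5] instead
of the mean.
"""

from __future__ import annotations

import pandas as pd

from .measures import MEASURES

#: valid keys for ranking: the five measures plus the index itself
RANKABLE = (*MEASURES, "epsi")


def compute_epsi(profiles: pd.DataFrame, divide_by_n: bool = True) -> pd.DataFrame:
    """Per-phenotype proportions and E-PSI from a severity-profile table.

    Returns a frame with ``phenotype_code``, one ``prop_<measure>`` column per
    measure, and ``epsi``.  Maxima are taken within the supplied table.
    """
    if profiles.empty:
        raise ValueError("profile table is empty; E-PSI undefined")
    out = profiles[["phenotype_code"]].copy()
    for m in MEASURES:
        mx = profiles[m].max()
        out[f"prop_{m}"] = profiles[m] / mx if mx > 0 else 0.0
    prop_cols = [f"prop_{m}" for m in MEASURES]
    total = out[prop_cols].sum(axis=1)
    out["epsi"] = total / len(MEASURES) if divide_by_n else total
    return out


def rank_phenotypes(
    table: pd.DataFrame, by: str, top_k: int | None = None
) -> list[str]:
    """Phenotype codes in descending order of a measure or of E-PSI.

    ``table`` may be a profile table, an E-PSI score table, or a merge of the
    two, as long as it contains the requested column.  Ties are broken
    lexicographically by code so rankings are deterministic.
    """
    if by not in RANKABLE:
        raise ValueError(f"unknown measure {by!r}; expected one of {RANKABLE}")
    if by not in table.columns:
        raise ValueError(f"table has no column {by!r}")
    ordered = table.sort_values(
        [by, "phenotype_code"], ascending=[False, True], kind="mergesort"
    )["phenotype_code"].tolist()
    return ordered if top_k is None else ordered[:top_k]
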