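"""LTR retrotransposon insertion-time dating from LTR-pair identity.

The two long terminal repeats of an LTR retrotransposon are identical at
insertion and diverge neutrally afterwards, so the element's age is
T = K / (2r), where K = 1 - identity is the raw divergence between the two
LTRs and r is the neutral mutation rate per site per year. The default rate
is 2.2e-9, a value commonly used for conifer genomes. Divergence is used
raw — no Jukes-Cantor or K2P multiple-hit correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MUTATION_RATE",
    "LtrDatingResult",
    "LtrRecord",
    "date_pass_list",
    "ltr_insertion_time",
    "normalize_identity",
]

DEFAULT_MUTATION_RATE = 2.2e-9  # substitutions per site per year

#: Values above this are taken to be percents and divided by 100. Identity
#: fractions cannot exceed 1 and percent identities of interest are well
#: above 1.5%, so the cut cleanly separates the two dialects.
_PERCENT_CUT = 1.5


def normalize_identity(value: float) -> float:
    """Normalize an identity given as fraction (0.9956) or percent (99.56).

    Raises
    ------
    ValueError
        If the value is not in [0, 1] after percent normalization.
    """
    x = float(value)
    if x > _PERCENT_CUT:
        x /= 100.0
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"identity {value!r} is outside [0, 1] after normalization")
    return x


def ltr_insertion_time(identity: float, r: float = DEFAULT_MUTATION_RATE) -> float:
    """Insertion time in years: T = K / (2r) with K = 1 - identity.

    ``identity`` may be a fraction or a percent (auto-detected).

    Raises
    ------
    ValueError
        If ``r <= 0`` or identity is out of range.
    """
    if r <= 0:
        raise ValueError(f"mutation rate must be positive, got {r}")
    ident = normalize_identity(identity)
    return (1.0 - ident) / (2.0 * r)


@dataclass(frozen=True)
class LtrRecord:
    """A dated intact LTR retrotransposon."""

    element_id: str
    identity: float  # fraction in [0, 1]
    K: float  # divergence, 1 - identity
    T: float  # insertion time, years
    r: float  # mutation rate used, per site per year

    @property
    def T_my(self) -> float:
        return self.T / 1e6


@dataclass
class LtrDatingResult:
    records: List[LtrRecord]
    histogram: pd.DataFrame  # columns: bin_start_my, bin_end_my, count
    n_skipped: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element_id": [r.element_id for r in self.records],
                "identity": [r.identity for r in self.records],
                "K": [r.K for r in self.records],
                "T_years": [r.T for r in self.records],
                "T_My": [r.T_my for r in self.records],
            }
        )


def date_pass_list(
    table: Union[str, pd.DataFrame],
    r: float = DEFAULT_MUTATION_RATE,
    bin_my: float = 0.5,
) -> LtrDatingResult:
    """Date every element of an LTR pass list by LTR-pair identity.

    ``table`` is a path to a tab-separated pass list (as produced by
    LTR-RETRIEVER, possibly with a leading ``#`` on the header) or an
    equivalent DataFrame. The identity column is located by name,
    case-insensitively; element IDs come from the first column. Rows whose
    identity does not parse are skipped and counted. Ages are histogrammed
    in bins of ``bin_my`` million years.

    Raises
    ------
    ValueError
        If no identity column is present (the message names the available
        columns) or ``bin_my <= 0``.
    """
    if bin_my <= 0:
        raise ValueError(f"bin_my must be positive, got {bin_my}")
    if isinstance(table, (str, bytes)) or hasattr(table, "__fspath__"):
        df = pd.read_csv(table, sep="\t", dtype=str)
        df.columns = [c.lstrip("#").strip() for c in df.columns]
    else:
        df = table.copy()
        df.columns = [str(c).lstrip("#").strip() for c in df.columns]
    ident_col = next(
        (c for c in df.columns if c.strip().lower() == "identity"), None
    )
    if ident_col is None:
        raise ValueError(
            f"no 'Identity' column found; available columns: {list(df.columns)}"
        )
    id_col = df.columns[0]
    records: List[LtrRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        try:
            ident = normalize_identity(float(row[ident_col]))
        except (TypeError, ValueError):
            skipped += 1
            continue
        t = (1.0 - ident) / (2.0 * r)
        records.append(LtrRecord(str(row[id_col]), ident, 1.0 - ident, t, r))
    ages_my = np.array([rec.T_my for rec in records])
    if ages_my.size:
        n_bins = max(1, int(np.ceil(ages_my.max() / bin_my)) or 1)
        edges = np.arange(n_bins + 1) * bin_my
        counts, _ = np.histogram(ages_my, bins=edges)
    else:
        edges = np.array([0.0, bin_my])
        counts = np.array([], dtype=int)
        edges = edges[:1]  # zero-bin histogram for empty input
    hist = pd.DataFrame(
        {
            "bin_start_my": edges[:-1] if len(edges) > 1 else np.array([]),
            "bin_end_my": edges[1:] if len(edges) > 1 else np.array([]),
            "count": counts,
        }
    )
    return LtrDatingResult(records=records, histogram=hist, n_skipped=skipped)
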