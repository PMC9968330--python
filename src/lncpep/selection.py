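"""Shortlisting lncRNA-derived peptides for vaccine inclusion.

Candidates are screened on three criteria: predicted high affinity for
MHC class I (low percentile rank from an external predictor), low
expression of the source lncRNA in normal thymocytes (so the peptide may
escape central tolerance), and significant differential regulation of
the source lncRNA under PRMT5 inhibition.  Thresholds are mandatory
configuration — there are no silent defaults — and survivors are ranked
lexicographically by (affinity rank, thymus expression, q-value), ties
broken by peptide string so the order is a deterministic total order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd


@dataclass(frozen=True)
class CandidateAnnotation:
    """External annotations for one candidate peptide.

    ``predicted_affinity_rank``: predictor percentile rank, lower =
    stronger binding.  ``thymus_expression``: expression of the source
    lncRNA in normal thymocytes (arbitrary units).  ``regulation_q``:
    q-value of the source lncRNA's differential regulation, with
    ``regulation_direction`` in {up, down}.
    """

    peptide: str
    predicted_affinity_rank: float
    thymus_expression: float
    regulation_q: float
    regulation_direction: str = ""


def rank_vaccine_candidates(
    annotations: Sequence[CandidateAnnotation],
    affinity_rank_max: float,
    thymus_max: float,
    q_max: float,
    n: int,
) -> list[CandidateAnnotation]:
    """Filter on all three thresholds, rank, and return the top ``n``.

    Candidates failing any threshold are excluded.  If fewer than ``n``
    survive, the shorter list is returned with a warning.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    survivors = [
        a
        for a in annotations
        if a.predicted_affinity_rank <= affinity_rank_max
        and a.thymus_expression <= thymus_max
        and a.regulation_q <= q_max
    ]
    survivors.sort(
        key=lambda a: (
            a.predicted_affinity_rank,
            a.thymus_expression,
            a.regulation_q,
            a.peptide,
        )
    )
    if len(survivors) < n:
        warnings.warn(
            f"only {len(survivors)} candidates satisfy the thresholds "
            f"(requested {n})"
        )
    return survivors[:n]


def annotations_from_frame(df: pd.DataFrame) -> list[CandidateAnnotation]:
    """Read candidate annotations from a table with columns
    peptide, affinity_rank, thymus_expression, q (optional direction)."""
    required = {"peptide", "affinity_rank", "thymus_expression", "q"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    return [
        CandidateAnnotation(
            peptide=str(r.peptide),
            predicted_affinity_rank=float(r.affinity_rank),
            thymus_expression=float(r.thymus_expression),
            regulation_q=float(r.q),
            regulation_direction=str(getattr(r, "direction", "")),
        )
        for r in df.itertuples(index=False)
    ]


def shortlist_to_frame(shortlist: Sequence[CandidateAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": range(1, len(shortlist) + 1),
            "peptide": [a.peptide for a in shortlist],
            "affinity_rank": [a.predicted_affinity_rank for a in shortlist],
            "thymus_expression": [a.thymus_expression for a in shortlist],
            "q": [a.regulation_q for a in shortlist],
            "direction": [a.regulation_direction for a in shortlist],
        }
    )
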