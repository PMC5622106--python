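"""Scan of immunoglobulin-superfamily domains for CH1-like composition.

For each domain X, the amino-acid composition vector is compared against
representative CH1 and CL compositions through the cosine of the angle
between the differenced vectors (X - CL_REF) and (CH1_REF - CL_REF): a
cosine near 1 means X deviates from CL in the same direction CH1 does. This
is combined with a low-sequence-entropy threshold — CH1 has atypically low
composition entropy — into a double criterion (cosine > 0.3 and entropy
< 3.83 bits by default) that flags candidate CH1-like domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqprops import (CompositionVector, DomainSequence, composition,
                       sequence_entropy)

#: Default double-threshold: cosine strictly above, entropy strictly below.
COSINE_THRESHOLD = 0.3
ENTROPY_THRESHOLD = 3.83


class DegenerateComparisonError(ValueError):
    """A differenced composition vector is zero; the cosine is undefined."""


@dataclass(frozen=True)
class ScanResult:
    """Cosine, entropy and threshold verdict for one scanned domain."""

    domain_id: str
    cosine: float
    entropy: float
    passes: bool

    def __post_init__(self) -> None:
        if not math.isnan(self.cosine) and \
                not -1.0 - 1e-12 <= self.cosine <= 1.0 + 1e-12:
            raise ValueError(f"cosine {self.cosine} outside [-1, 1]")


def composition_difference_cosine(X: CompositionVector,
                                  ch1_ref: CompositionVector,
                                  cl_ref: CompositionVector) -> float:
    """cos of the angle between (X - CL_REF) and (CH1_REF - CL_REF)."""
    a = X.as_array() - cl_ref.as_array()
    b = ch1_ref.as_array() - cl_ref.as_array()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateComparisonError("degenerate comparison: zero differenced vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def scan_igsf(domains: Iterable[DomainSequence],
              ch1_ref: CompositionVector,
              cl_ref: CompositionVector,
              cosine_threshold: float = COSINE_THRESHOLD,
              entropy_threshold: float = ENTROPY_THRESHOLD) -> list[ScanResult]:
    """Scan a domain cohort; results ranked by cosine descending, id tie-break.

    A domain passes iff cosine > cosine_threshold and entropy <
    entropy_threshold (strict comparisons). A domain whose composition
    coincides with CL_REF has no defined direction; it is reported with a
    NaN cosine (ranked last) and cannot pass.
    """
    results = []
    for dom in domains:
        comp = composition(dom)
        try:
            cos = composition_difference_cosine(comp, ch1_ref, cl_ref)
        except DegenerateComparisonError:
            cos = float("nan")
        ent = sequence_entropy(comp)
        results.append(ScanResult(dom.id, cos, ent,
                                  cos > cosine_threshold and ent < entropy_threshold))
    results.sort(key=lambda r: (math.isnan(r.cosine), -r.cosine
                                if not math.isnan(r.cosine) else 0.0,
                                r.domain_id))
    return results


def scan_table(results: Sequence[ScanResult]) -> pd.DataFrame:
    return pd.DataFrame([{"id": r.domain_id, "cosine": r.cosine,
                          "entropy": r.entropy, "passes": r.passes}
                         for r in results])


def write_scan_tsv(results: Sequence[ScanResult], path) -> pd.DataFrame:
    df = scan_table(results)
    df.to_csv(path, sep="\t", index=False)
    return df
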