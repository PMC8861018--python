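"""Allele-fraction computation and 2:2 / 1:3 genotype-class timing model.

A germline DNM fixed before gamete formation is an ordinary heterozygous
variant in the offspring: two of the four strands after zygotic genome
replication carry it, so the expected variant allele fraction (VAF) is
0.5 — the 2:2 class.  A mismatch left unrepaired until meiosis or the
first zygotic division segregates to only one of the four strands,
giving an expected VAF of 0.25 — the 1:3 class.

Classification is descriptive, on the raw observed VAF: 0.30–0.70 is
called 2:2, 0.10–0.30 is called 1:3.  The shared boundary at 0.30 is
assigned to the 2:2 interval (half-open convention, configurable), and
VAFs outside [0.10, 0.70] stay unclassified.  Exact binomial machinery
quantifies how often sequencing noise at finite depth crosses the
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

CLASS_22 = "2:2"
CLASS_13 = "1:3"
CLASS_UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class GenotypeClassRule:
    """VAF intervals: [lo_13, lo_11) -> 1:3, [lo_11, hi_11] -> 2:2."""

    lo_13: float = 0.10
    lo_11: float = 0.30
    hi_11: float = 0.70

    def __post_init__(self) -> None:
        if not 0 < self.lo_13 < self.lo_11 < self.hi_11 < 1:
            raise ValueError("require 0 < lo_13 < lo_11 < hi_11 < 1")


DEFAULT_RULE = GenotypeClassRule()


def vaf(alt_depth: float, total_depth: float) -> float:
    if total_depth <= 0:
        raise ValueError("total depth must be positive")
    value = alt_depth / total_depth
    if not 0 <= value <= 1:
        raise ValueError("alt depth outside [0, total depth]")
    return value


def classify_genotype(observed_vaf: float,
                      rule: GenotypeClassRule = DEFAULT_RULE) -> str:
    if not 0 <= observed_vaf <= 1:
        raise ValueError("VAF must lie in [0, 1]")
    if rule.lo_11 <= observed_vaf <= rule.hi_11:
        return CLASS_22
    if rule.lo_13 <= observed_vaf < rule.lo_11:
        return CLASS_13
    return CLASS_UNCLASSIFIED


def classify_table(dnms: pd.DataFrame,
                   rule: GenotypeClassRule = DEFAULT_RULE) -> pd.DataFrame:
    """Fill the ``genotype_class`` column of a DNM table from its
    ``vaf`` column."""
    out = dnms.copy()
    out["genotype_class"] = [classify_genotype(v, rule) for v in out["vaf"]]
    return out


def timing_summary(dnms: pd.DataFrame) -> dict:
    """Counts and fractions of the genotype classes, overall and per
    sample."""
    classes = [CLASS_22, CLASS_13, CLASS_UNCLASSIFIED]
    if dnms.empty:
        return {"counts": {c: 0 for c in classes},
                "fractions": {c: 0.0 for c in classes},
                "total": 0, "per_sample": {}}
    counts = dnms["genotype_class"].value_counts()
    total = int(counts.sum())
    per_sample = {
        sid: group["genotype_class"].value_counts()
        .reindex(classes, fill_value=0).to_dict()
        for sid, group in dnms.groupby("sample_id")}
    return {
        "counts": {c: int(counts.get(c, 0)) for c in classes},
        "fractions": {c: counts.get(c, 0) / total for c in classes},
        "total": total,
        "per_sample": per_sample,
    }


def expected_misclassification(rule: GenotypeClassRule, true_vaf: float,
                               depth: int) -> float:
    """Exact probability that binomial read sampling at ``depth`` pushes
    the observed VAF of a variant with true VAF ``true_vaf`` outside its
    own class interval.

    E.g. for the 1:3 class (true VAF 0.25) at depth 30 this is
    P(X <= 2) + P(X >= 9) with X ~ Binomial(30, 0.25).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    true_class = classify_genotype(true_vaf, rule)
    if true_class == CLASS_UNCLASSIFIED:
        raise ValueError("true VAF falls in no genotype class")
    k = np.arange(depth + 1)
    observed = k / depth
    if true_class == CLASS_22:
        inside = (observed >= rule.lo_11) & (observed <= rule.hi_11)
    else:
        inside = (observed >= rule.lo_13) & (observed < rule.lo_11)
    pmf = sps.binom.pmf(k, depth, true_vaf)
    return float(pmf[~inside].sum())
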