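"""Coverage-based screening of externally called structural variants.

SV discovery itself (split-read / read-pair callers) is out of scope;
this module applies the post-hoc keep rules to candidate tables:

* depths are normalised so the samples of a sibship share a common mean;
* candidates overlapping centromere/telomere-proximal intervals are
  dropped;
* a candidate is kept only if its region depth deviates from BOTH the
  sample's genome-wide mean and the flanking-region depth by at least
  half of the respective reference value;
* a kept F2 candidate is flagged as potentially de novo when its region
  depth differs from at least one parent's depth over the same region by
  0.5x that parent's depth or more (boundary inclusive).

All decisions depend only on depth ratios, never on the absolute scale.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import IntervalMap

SV_COLUMNS = ["sample_id", "chrom", "start", "end", "sv_type",
              "region_depth", "flank_depth", "genome_mean_depth"]

DEPTH_COLUMNS = ["region_depth", "flank_depth", "genome_mean_depth",
                 "father_depth", "mother_depth"]


def _validate(candidates: pd.DataFrame) -> None:
    if candidates.empty:
        return
    if (candidates["end"] <= candidates["start"]).any():
        raise ValueError("SV candidate with end <= start")


def normalize_depths(candidates: pd.DataFrame,
                     sibship_by_sample: Mapping[str, str]) -> pd.DataFrame:
    """Scale each sample's depth columns so all samples of a sibship
    share the sibship's mean genome-wide depth."""
    _validate(candidates)
    if candidates.empty:
        return candidates.copy()
    out = candidates.copy()
    sample_mean = out.groupby("sample_id")["genome_mean_depth"].first()
    if (sample_mean <= 0).any():
        bad = sample_mean[sample_mean <= 0].index.tolist()
        raise ValueError(f"zero mean depth for samples: {bad}")
    sibship = sample_mean.index.to_series().map(sibship_by_sample)
    if sibship.isna().any():
        raise KeyError("sample without sibship assignment")
    target = sample_mean.groupby(sibship).transform("mean")
    factor = (target / sample_mean).rename("factor")
    f = out["sample_id"].map(factor)
    for col in DEPTH_COLUMNS:
        if col in out.columns:
            out[col] = out[col] * f
    return out


def filter_sv_candidates(candidates: pd.DataFrame,
                         excluded_regions: IntervalMap,
                         deviation: float = 0.5) -> pd.DataFrame:
    """Apply the exclusion-region and coverage-deviation keep rules."""
    _validate(candidates)
    if candidates.empty:
        return candidates.copy()
    trees = {chrom: IntervalTree.from_tuples(ivs)
             for chrom, ivs in excluded_regions.items() if ivs}
    outside = np.fromiter(
        (not (trees.get(c) and trees[c].overlap(s, e))
         for c, s, e in zip(candidates["chrom"], candidates["start"],
                            candidates["end"])),
        dtype=bool, count=len(candidates))
    genome_dev = (candidates["region_depth"]
                  - candidates["genome_mean_depth"]).abs() \
        >= deviation * candidates["genome_mean_depth"]
    flank_dev = (candidates["region_depth"]
                 - candidates["flank_depth"]).abs() \
        >= deviation * candidates["flank_depth"]
    return candidates[outside & genome_dev & flank_dev].copy()


def flag_de_novo_svs(candidates: pd.DataFrame,
                     difference: float = 0.5) -> pd.DataFrame:
    """Add a ``de_novo_flag`` column: region depth differs from at least
    one parent's depth by >= ``difference`` x that parent's depth.

    ``candidates`` must carry ``father_depth`` and ``mother_depth``
    (parental read depth over the candidate region); missing values
    raise.
    """
    _validate(candidates)
    out = candidates.copy()
    if out.empty:
        out["de_novo_flag"] = pd.Series(dtype=bool)
        return out
    for col in ("father_depth", "mother_depth"):
        if col not in out.columns or out[col].isna().any():
            raise KeyError(f"missing parental depth column {col}")
    father = (out["region_depth"] - out["father_depth"]).abs() \
        >= difference * out["father_depth"]
    mother = (out["region_depth"] - out["mother_depth"]).abs() \
        >= difference * out["mother_depth"]
    out["de_novo_flag"] = father | mother
    return out


def size_distribution(candidates: pd.DataFrame,
                      bins: np.ndarray | list[float] | int = 10,
                      ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Length histogram per SV type; returns ``{type: (counts, edges)}``."""
    _validate(candidates)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if candidates.empty:
        return out
    lengths = candidates["end"] - candidates["start"]
    for sv_type, idx in candidates.groupby("sv_type").groups.items():
        counts, edges = np.histogram(lengths.loc[idx], bins=bins)
        out[str(sv_type)] = (counts, edges)
    return out
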