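"""SNV qualification rules.

A qualified SNV must (1) sit at a proper sequencing depth — inside the
hard 20–60x window AND within three standard deviations of the sample's
mean coverage; (2) have its mutant allele supported by at least three
reads; (3) carry a site quality of at least 30; (4) show mean mapping
quality strictly above 30 on both alleles; and (5) fall outside tandem-
repeat regions.

The depth/quality boundary conventions: "minimum quality of 30" is read
as inclusive (>= 30), "exceeds 30" as strict (> 30).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import GenomeModel, IntervalMap

RULE_DEPTH = "depth"
RULE_ALT_SUPPORT = "alt_support"
RULE_SITE_QUALITY = "site_quality"
RULE_MAPPING_QUALITY = "mapping_quality"
RULE_REPEAT_MASK = "repeat_mask"
RULE_ORDER = [RULE_DEPTH, RULE_ALT_SUPPORT, RULE_SITE_QUALITY,
              RULE_MAPPING_QUALITY, RULE_REPEAT_MASK]


@dataclass(frozen=True)
class FilterThresholds:
    depth_lo: int = 20
    depth_hi: int = 60
    n_sd: float = 3.0
    min_alt_reads: int = 3
    min_site_quality: float = 30.0
    min_mapping_quality: float = 30.0  # strict bound


def passes_depth(total_depth: float, mean_depth: float, sd_depth: float,
                 thresholds: FilterThresholds = FilterThresholds()) -> bool:
    """Hard 20–60x window AND |depth − mean| <= n_sd·sd."""
    if mean_depth <= 0 or sd_depth < 0:
        raise ValueError("mean depth must be > 0 and sd >= 0")
    t = thresholds
    return (t.depth_lo <= total_depth <= t.depth_hi
            and abs(total_depth - mean_depth) <= t.n_sd * sd_depth)


def passes_alt_support(alt_depth: int,
                       thresholds: FilterThresholds = FilterThresholds()) -> bool:
    if alt_depth < 0:
        raise ValueError("alt depth must be >= 0")
    return alt_depth >= thresholds.min_alt_reads


def passes_quality(site_quality: float, mq_ref: float, mq_alt: float,
                   thresholds: FilterThresholds = FilterThresholds()) -> bool:
    if min(site_quality, mq_ref, mq_alt) < 0:
        raise ValueError("qualities must be >= 0")
    t = thresholds
    return (site_quality >= t.min_site_quality
            and mq_ref > t.min_mapping_quality
            and mq_alt > t.min_mapping_quality)


def coverage_stats(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean and standard deviation of record depth.

    Used as the coverage profile when no genome-wide profile is
    supplied.
    """
    g = calls.groupby("sample_id")["total_depth"]
    out = pd.DataFrame({"mean_depth": g.mean(), "sd_depth": g.std(ddof=0)})
    out["sd_depth"] = out["sd_depth"].fillna(0.0)
    return out


def _mask_trees(mask: IntervalMap) -> dict[str, IntervalTree]:
    return {chrom: IntervalTree.from_tuples(ivs)
            for chrom, ivs in mask.items() if ivs}


def in_mask(chrom: str, pos: int, trees: dict[str, IntervalTree]) -> bool:
    """1-based position vs 0-based half-open intervals."""
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlaps_point(pos - 1))


def apply_repeat_mask(variants: pd.DataFrame, mask: IntervalMap,
                      genome: GenomeModel | None = None) -> pd.DataFrame:
    """Drop variants whose position overlaps a mask interval; order
    preserved."""
    if genome is not None:
        lengths = genome.lengths
        for chrom, ivs in mask.items():
            for start, end in ivs:
                if chrom in lengths and end > lengths[chrom]:
                    raise ValueError(
                        f"mask interval [{start},{end}) beyond end of {chrom}")
    if variants.empty or not mask:
        return variants.copy()
    trees = _mask_trees(mask)
    keep = [not in_mask(c, p, trees)
            for c, p in zip(variants["chrom"], variants["pos"])]
    return variants[np.asarray(keep)].copy()


def is_snv(ref: pd.Series, alt: pd.Series) -> pd.Series:
    return (ref.str.len() == 1) & (alt.str.len() == 1)


def filter_variants(calls: pd.DataFrame,
                    coverage: pd.DataFrame | None = None,
                    mask: IntervalMap | None = None,
                    thresholds: FilterThresholds = FilterThresholds(),
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the five qualification rules to a long-format call table.

    Returns ``(kept, rejected)``; ``rejected`` carries a ``reason``
    column naming the first failing rule in the canonical order (the
    kept set itself is the order-independent conjunction of all rules).
    Indels bypass the SNV rules: they are kept and flagged in an
    ``is_indel`` column.

    ``coverage`` is a per-sample frame with ``mean_depth``/``sd_depth``
    (computed from the calls themselves when omitted).
    """
    if calls.empty:
        kept = calls.copy()
        kept["is_indel"] = pd.Series(dtype=bool)
        rejected = calls.copy()
        rejected["reason"] = pd.Series(dtype=object)
        return kept, rejected
    if coverage is None:
        coverage = coverage_stats(calls)
    unknown = set(calls["sample_id"]) - set(coverage.index)
    if unknown:
        raise KeyError(f"no coverage stats for samples: {sorted(unknown)}")

    df = calls.merge(coverage, left_on="sample_id", right_index=True,
                     how="left")
    t = thresholds
    snv = is_snv(df["ref"], df["alt"])

    ok_depth = ((df["total_depth"] >= t.depth_lo)
                & (df["total_depth"] <= t.depth_hi)
                & ((df["total_depth"] - df["mean_depth"]).abs()
                   <= t.n_sd * df["sd_depth"]))
    ok_alt = df["alt_depth"] >= t.min_alt_reads
    ok_qual = df["qual"] >= t.min_site_quality
    ok_mq = (df["mq_ref"] > t.min_mapping_quality) \
        & (df["mq_alt"] > t.min_mapping_quality)
    if mask:
        trees = _mask_trees(mask)
        outside = np.fromiter(
            (not in_mask(c, p, trees)
             for c, p in zip(df["chrom"], df["pos"])),
            dtype=bool, count=len(df))
        ok_mask = pd.Series(outside, index=df.index)
    else:
        ok_mask = pd.Series(True, index=df.index)

    rules = {RULE_DEPTH: ok_depth, RULE_ALT_SUPPORT: ok_alt,
             RULE_SITE_QUALITY: ok_qual, RULE_MAPPING_QUALITY: ok_mq,
             RULE_REPEAT_MASK: ok_mask}
    pass_all = snv & ok_depth & ok_alt & ok_qual & ok_mq & ok_mask

    reason = pd.Series("", index=df.index, dtype=object)
    for name in reversed(RULE_ORDER):  # earlier rules overwrite later ones
        reason[snv & ~rules[name]] = name

    keep = pass_all | ~snv
    kept = calls[keep].copy()
    kept["is_indel"] = ~snv[keep].to_numpy()
    rejected = calls[~keep].copy()
    rejected["reason"] = reason[~keep].to_numpy()
    return kept, rejected
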