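"""De novo mutation calling over a three-generation pedigree.

A de novo mutation (DNM) in a focal F1 or F2 sample is a qualified
variant present in that sample and absent — under a deliberately lenient
presence criterion — from its parents and from every sequenced earlier-
generation member of its sibship.  Using all three generations of the
sibship as the exclusion set maximally suppresses inherited variants
that merely failed QC in one parent.

Ancestral variants shared by every sibship (or present in unrelated
control animals) are removed up front: they are fixed differences from
the reference, not new mutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .pedigree import Pedigree
from .stats import substitution_class
from .vcfio import VARIANT_KEY

DNM_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "vaf",
               "total_depth", "alt_depth", "genotype_class",
               "substitution_class"]

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class PresenceRule:
    """When is a variant 'observed' in a sample?  Any of: at least
    ``min_alt_reads`` alternate reads, or an observed allele fraction of
    at least ``min_vaf`` at depth >= ``min_depth``.  Deliberately more
    lenient than the candidate filter."""

    min_alt_reads: int = 2
    min_vaf: float = 0.05
    min_depth: int = 10


def variant_present(alt_depth, total_depth,
                    rule: PresenceRule = PresenceRule()):
    """Vectorised presence criterion; accepts scalars or arrays."""
    alt = np.asarray(alt_depth)
    dp = np.asarray(total_depth)
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(dp > 0, alt / np.maximum(dp, 1), 0.0)
    present = (alt >= rule.min_alt_reads) | (
        (vaf >= rule.min_vaf) & (dp >= rule.min_depth))
    return bool(present) if present.ndim == 0 else present


def _present_keys(raw: pd.DataFrame, sample_id: str,
                  rule: PresenceRule) -> set[VariantKey]:
    sub = raw[raw["sample_id"] == sample_id]
    mask = variant_present(sub["alt_depth"].to_numpy(),
                           sub["total_depth"].to_numpy(), rule)
    return set(map(tuple, sub.loc[mask, VARIANT_KEY].itertuples(index=False)))


def call_dnms(focal_id: str, pedigree: Pedigree, qualified: pd.DataFrame,
              raw: pd.DataFrame | None = None,
              rule: PresenceRule = PresenceRule()) -> pd.DataFrame:
    """Call DNMs for one focal sample.

    ``qualified`` is the filtered call table (candidates come from
    here); ``raw`` is the unfiltered table used to judge presence in
    relatives (defaults to ``qualified``).  Raises ``KeyError`` naming
    the sample if a parent has no records in ``raw``.
    """
    if focal_id not in pedigree:
        raise KeyError(f"unknown focal sample {focal_id}")
    if not pedigree.parents_of(focal_id):
        raise ValueError(
            f"sample {focal_id} has no sequenced parents; de novo status "
            "is undefined for founders")
    if raw is None:
        raw = qualified
    relatives = {s.sample_id for s in pedigree.parents_of(focal_id)}
    relatives |= {s.sample_id
                  for s in pedigree.ancestors_in_sibship(focal_id)}
    raw_samples = set(raw["sample_id"].unique())
    for parent in pedigree.parents_of(focal_id):
        if parent.sample_id not in raw_samples:
            raise KeyError(
                f"no variant table for parent {parent.sample_id} "
                f"of {focal_id}")

    excluded: set[VariantKey] = set()
    for rel in sorted(relatives):
        excluded |= _present_keys(raw, rel, rule)

    focal = qualified[qualified["sample_id"] == focal_id]
    # candidate must itself be present in the focal sample
    focal = focal[variant_present(focal["alt_depth"].to_numpy(),
                                  focal["total_depth"].to_numpy(), rule)]
    keys = list(map(tuple, focal[VARIANT_KEY].itertuples(index=False)))
    keep = [k not in excluded for k in keys]
    dnms = focal[np.asarray(keep, dtype=bool)] if keys else focal

    out = pd.DataFrame({
        "sample_id": dnms["sample_id"],
        "chrom": dnms["chrom"],
        "pos": dnms["pos"],
        "ref": dnms["ref"],
        "alt": dnms["alt"],
        "vaf": dnms["alt_depth"] / dnms["total_depth"],
        "total_depth": dnms["total_depth"],
        "alt_depth": dnms["alt_depth"],
    })
    out["genotype_class"] = "unclassified"
    out["substitution_class"] = [
        substitution_class(r, a) if len(r) == 1 and len(a) == 1 else "indel"
        for r, a in zip(out["ref"], out["alt"])]
    return out.reset_index(drop=True)[DNM_COLUMNS]


def remove_shared_snvs(sibship_sets: Mapping[str, Iterable[VariantKey]],
                       control_set: Iterable[VariantKey] = (),
                       ) -> tuple[dict[str, set[VariantKey]], set[VariantKey]]:
    """Remove ancestral variants: those present in every sibship, or in
    any control sample, are deleted from all candidate sets.

    Returns ``(filtered_sets, removed)``.
    """
    sets = {k: set(v) for k, v in sibship_sets.items()}
    controls = set(control_set)
    if len(sets) < 2 and not controls:
        raise ValueError(
            "need at least two sibships or a control set to identify "
            "ancestrally shared variants")
    shared = set.intersection(*sets.values()) if len(sets) >= 2 else set()
    removed = shared | controls
    return ({k: v - removed for k, v in sets.items()}, removed)


def remove_shared_from_calls(qualified: pd.DataFrame, pedigree: Pedigree,
                             rule: PresenceRule = PresenceRule(),
                             ) -> tuple[pd.DataFrame, set[VariantKey]]:
    """Frame-level wrapper: build per-sibship presence sets and the
    control presence set from the qualified calls, then drop the
    ancestrally shared variants from the table."""
    sibship_sets: dict[str, set[VariantKey]] = {}
    for sib in pedigree.sibship_ids:
        keys: set[VariantKey] = set()
        for s in pedigree.sibship(sib):
            keys |= _present_keys(qualified, s.sample_id, rule)
        sibship_sets[sib] = keys
    control_keys: set[VariantKey] = set()
    for s in pedigree.controls:
        control_keys |= _present_keys(qualified, s.sample_id, rule)
    _, removed = remove_shared_snvs(sibship_sets, control_keys)
    if not removed:
        return qualified.copy(), removed
    keys = list(map(tuple, qualified[VARIANT_KEY].itertuples(index=False)))
    keep = np.array([k not in removed for k in keys], dtype=bool)
    return qualified[keep].copy(), removed


# ---------------------------------------------------------------------------
# sex inference from sex-chromosome coverage

@dataclass(frozen=True)
class SexThresholds:
    y_male_min: float = 0.25
    y_female_max: float = 0.05
    x_female_min: float = 0.75
    x_male_max: float = 0.75


def infer_sex(chrom_depths: Mapping[str, float], genome: GenomeModel,
              thresholds: SexThresholds = SexThresholds()) -> str:
    """Classify a sample as male/female/ambiguous from per-chromosome
    mean depths: males show X and Y at about half the autosome depth,
    females a full-depth X and near-zero Y."""
    for name in (genome.x_name, genome.y_name):
        if name not in chrom_depths:
            raise KeyError(f"missing sex chromosome {name} in coverage")
    autosomes = [chrom_depths[c] for c in genome.autosome_names
                 if c in chrom_depths]
    if not autosomes:
        raise KeyError("no autosome coverage available")
    auto = float(np.mean(autosomes))
    if auto <= 0:
        raise ValueError("autosome mean depth must be positive")
    x_ratio = chrom_depths[genome.x_name] / auto
    y_ratio = chrom_depths[genome.y_name] / auto
    t = thresholds
    if y_ratio >= t.y_male_min and x_ratio <= t.x_male_max:
        return "male"
    if y_ratio <= t.y_female_max and x_ratio >= t.x_female_min:
        return "female"
    return "ambiguous"


def infer_sexes(coverage: pd.DataFrame, genome: GenomeModel,
                thresholds: SexThresholds = SexThresholds()) -> pd.Series:
    """Apply :func:`infer_sex` to a long coverage frame
    (``sample_id, chrom, mean_depth``)."""
    out = {}
    for sid, group in coverage.groupby("sample_id"):
        depths = dict(zip(group["chrom"], group["mean_depth"]))
        out[sid] = infer_sex(depths, genome, thresholds)
    return pd.Series(out, name="inferred_sex")


# ---------------------------------------------------------------------------
# summaries

def count_dnms_by_sample(dnms: pd.DataFrame, pedigree: Pedigree,
                         sex_by_sample: Mapping[str, str] | None = None,
                         ) -> dict:
    """Per-sample DNM counts (zero-filled over F1/F2 samples), per-
    sibship F2 means, and counts split by sex."""
    focal_ids = [s.sample_id for s in pedigree
                 if s.generation in ("F1", "F2")
                 and s.sibship_id != "control"]
    counts = (dnms["sample_id"].value_counts()
              .reindex(focal_ids, fill_value=0) if len(dnms)
              else pd.Series(0, index=focal_ids))
    f2 = [s for s in pedigree.generation("F2")]
    per_sibship = {}
    for sib in pedigree.sibship_ids:
        ids = [s.sample_id for s in f2 if s.sibship_id == sib]
        per_sibship[sib] = float(counts.reindex(ids, fill_value=0).mean()) \
            if ids else 0.0
    sexes = sex_by_sample or {s.sample_id: s.sex for s in pedigree}
    by_sex: dict[str, list[int]] = {}
    for s in f2:
        sex = sexes.get(s.sample_id, "unknown")
        by_sex.setdefault(sex, []).append(int(counts.get(s.sample_id, 0)))
    return {"per_sample": counts, "per_sibship_f2_mean": per_sibship,
            "f2_counts_by_sex": by_sex,
            "f2_mean": float(counts.reindex(
                [s.sample_id for s in f2], fill_value=0).mean())
            if f2 else 0.0}
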