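"""Synthetic three-generation pedigree study generator.

Emulates the data structure of a two-generation folate-deprivation mouse
cross: F0 grandparent pairs, focal FD-diet F1 males mated to
folate-sufficient partners, and F2 embryos sequenced at ~30x.  Each F2
carries a Poisson number of injected de novo mutations of known timing
class:

* ``pgc_fixed`` — fixed before gamete formation, true allele fraction
  0.5 (the 2:2 genotype);
* ``unrepaired_mismatch`` — an unrepaired DNA mismatch segregating at
  meiosis or in the zygote, true allele fraction 0.25 (the 1:3 genotype).

Read-level observation is binomial sampling of the true allele fraction
at a Poisson depth.  The generator also plants founder heterozygous
variants (Mendelian background), ancestral variants shared by every
sample (for root-filter testing), and writes VCF/PED/BED/TSV fixtures
plus a truth table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import vcfio
from .genome import GenomeModel, random_repeat_mask, sample_positions, write_bed
from .pedigree import Pedigree, PedigreeSample, build_pedigree
from .stats import CLASS_SUBSTITUTIONS, SPECTRUM_CLASSES, substitution_class

TIMING_PGC = "pgc_fixed"
TIMING_MISMATCH = "unrepaired_mismatch"

#: Control-arm substitution spectrum.  The focal G:C>A:T proportion (53%)
#: is the reported normal-diet germline value; the remaining classes
#: follow the usual germline shape (transitions over transversions).
CONTROL_SPECTRUM = {
    "G:C>A:T": 0.530, "A:T>G:C": 0.170, "G:C>T:A": 0.100,
    "G:C>C:G": 0.060, "A:T>T:A": 0.070, "A:T>C:G": 0.070,
}

#: Folate-deficient spectrum: focal class at 35.4%, the non-focal classes
#: rescaled proportionally from the control shape.
FD_SPECTRUM = {
    "G:C>A:T": 0.354,
    "A:T>G:C": 0.170 / 0.470 * 0.646,
    "G:C>T:A": 0.100 / 0.470 * 0.646,
    "G:C>C:G": 0.060 / 0.470 * 0.646,
    "A:T>T:A": 0.070 / 0.470 * 0.646,
    "A:T>C:G": 0.070 / 0.470 * 0.646,
}

TRUTH_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "timing",
                 "true_vaf", "substitution_class"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults are the study conditions: DNM means of 29.16 (spontaneous
    expectation), 87.6 (one FD grandparent) and 211 (both FD
    grandparents) per F2; 77/2 per F1; mismatch-class probability
    268/575; ~30x depth; control vs FD six-class spectra with G:C>A:T
    at 53% vs 35.4%.
    """

    genome: GenomeModel = field(default_factory=GenomeModel.mouse_desk_scale)
    group: str = "B"
    n_sibships: int = 3
    n_f2_per_sibship: int = 8
    n_controls: int = 4
    lambda_control: float = 29.16
    lambda_one_fd: float = 87.6
    lambda_both_fd: float = 211.0
    lambda_f1: float = 38.5
    p_mismatch: float = 268 / 575
    spectrum_fd: dict[str, float] = field(
        default_factory=lambda: dict(FD_SPECTRUM))
    spectrum_control: dict[str, float] = field(
        default_factory=lambda: dict(CONTROL_SPECTRUM))
    depth_mean: float = 30.0
    n_founder_het: int = 100
    n_shared_ancestral_snvs: int = 25
    qual_range: tuple[float, float] = (40.0, 60.0)
    mq_range: tuple[float, float] = (50.0, 60.0)
    noisy: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for lam in (self.lambda_control, self.lambda_one_fd,
                    self.lambda_both_fd, self.lambda_f1):
            if lam < 0:
                raise ValueError("DNM means must be non-negative")
        if not 0 <= self.p_mismatch <= 1:
            raise ValueError("p_mismatch must lie in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        for probs in (self.spectrum_fd, self.spectrum_control):
            if set(probs) != set(SPECTRUM_CLASSES):
                raise ValueError("spectrum must cover the six classes")
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ValueError("spectrum must sum to 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError("spectrum probabilities must be >= 0")

    @property
    def lambda_f2(self) -> float:
        """F2 DNM mean implied by the diet group."""
        return self.lambda_both_fd if self.group == "C" else self.lambda_one_fd

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["genome"] = {"chromosomes": self.genome.chromosomes,
                       "x_name": self.genome.x_name,
                       "y_name": self.genome.y_name}
        return d


# ---------------------------------------------------------------------------
# elementary draws

def draw_substitution(spectrum: dict[str, float],
                      rng: np.random.Generator,
                      size: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``size`` (ref, alt) pairs: class from the spectrum, then one
    of the class's two strand representatives uniformly."""
    probs = np.array([spectrum[c] for c in SPECTRUM_CLASSES])
    cls_idx = rng.choice(len(SPECTRUM_CLASSES), size=size, p=probs)
    strand = rng.integers(0, 2, size=size)
    refs = np.empty(size, dtype="<U1")
    alts = np.empty(size, dtype="<U1")
    for i, (ci, si) in enumerate(zip(cls_idx, strand)):
        ref, alt = CLASS_SUBSTITUTIONS[SPECTRUM_CLASSES[ci]][si]
        refs[i] = ref
        alts[i] = alt
    return refs, alts


def simulate_reads(true_vaf: float | np.ndarray, depth_mean: float,
                   rng: np.random.Generator,
                   size: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sample (total_depth, alt_depth) observations for one or more true
    allele fractions: depth ~ Poisson(depth_mean) truncated at >= 1,
    alt_depth ~ Binomial(depth, true_vaf)."""
    vaf = np.atleast_1d(np.asarray(true_vaf, dtype=float))
    if size is not None and vaf.size == 1:
        vaf = np.full(size, vaf[0])
    if ((vaf < 0) | (vaf > 1)).any():
        raise ValueError("true allele fraction must lie in [0, 1]")
    depth = rng.poisson(depth_mean, size=vaf.size)
    while True:
        zero = depth == 0
        if not zero.any():
            break
        depth[zero] = rng.poisson(depth_mean, size=int(zero.sum()))
    alt = rng.binomial(depth, vaf)
    return depth.astype(np.int64), alt.astype(np.int64)


def draw_site_qualities(n: int, config: SimConfig,
                        rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Site quality and per-allele mapping qualities.  Defaults pass the
    SNV filters; ``noisy`` mode straddles the filter boundaries."""
    if config.noisy:
        qual = rng.uniform(20.0, 60.0, size=n)
        mq_ref = rng.uniform(20.0, 60.0, size=n)
        mq_alt = rng.uniform(20.0, 60.0, size=n)
    else:
        qual = rng.uniform(*config.qual_range, size=n)
        mq_ref = rng.uniform(*config.mq_range, size=n)
        mq_alt = rng.uniform(*config.mq_range, size=n)
    return qual, mq_ref, mq_alt


def inject_dnms(sample_id: str, lam: float, p_mismatch: float,
                spectrum: dict[str, float], genome: GenomeModel,
                rng: np.random.Generator,
                exclude_positions: set[tuple[str, int]] | None = None
                ) -> pd.DataFrame:
    """Draw a Poisson(lam) number of de novo mutations for one sample.

    Positions are uniform over the unmasked genome avoiding
    ``exclude_positions``; each mutation is an unrepaired mismatch
    (true allele fraction 0.25) with probability ``p_mismatch`` and
    otherwise PGC-fixed (0.5); ref/alt drawn from ``spectrum``.
    Returns a truth table (``TRUTH_COLUMNS``).
    """
    if lam < 0:
        raise ValueError("expected DNM count must be >= 0")
    n = int(rng.poisson(lam))
    if n == 0:
        return pd.DataFrame(columns=TRUTH_COLUMNS)
    positions = sample_positions(genome, n, rng,
                                 exclude=exclude_positions or set())
    refs, alts = draw_substitution(spectrum, rng, n)
    mismatch = rng.random(n) < p_mismatch
    return pd.DataFrame({
        "sample_id": sample_id,
        "chrom": [c for c, _ in positions],
        "pos": [p for _, p in positions],
        "ref": refs,
        "alt": alts,
        "timing": np.where(mismatch, TIMING_MISMATCH, TIMING_PGC),
        "true_vaf": np.where(mismatch, 0.25, 0.5),
        "substitution_class": [substitution_class(r, a)
                               for r, a in zip(refs, alts)],
    })


# ---------------------------------------------------------------------------
# inherited background

def simulate_inherited_variants(pedigree: Pedigree, config: SimConfig,
                                rng: np.random.Generator) -> pd.DataFrame:
    """Founder heterozygous variants transmitted by fair Mendelian draws,
    plus a block of ancestral variants carried by every sample.

    Returns a long table ``(chrom, pos, ref, alt, sample_id, true_vaf,
    origin)`` with one row per carrier; ``origin`` is ``founder`` or
    ``ancestral``.
    """
    founders = [s for s in pedigree if s.is_founder]
    n_sites = config.n_founder_het * len(founders) + config.n_shared_ancestral_snvs
    if n_sites == 0:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt",
                                     "sample_id", "true_vaf", "origin"])
    positions = sample_positions(config.genome, n_sites, rng)
    refs, alts = draw_substitution(config.spectrum_control, rng, n_sites)
    rows: list[tuple] = []
    cursor = 0

    children = {s.sample_id: [c for c in pedigree
                              if s.sample_id in (c.mother_id, c.father_id)]
                for s in pedigree}

    def transmit(carrier_id: str, site: tuple[str, int, str, str]) -> None:
        chrom, pos, ref, alt = site
        rows.append((chrom, pos, ref, alt, carrier_id, 0.5, "founder"))
        for child in children[carrier_id]:
            if rng.random() < 0.5:
                transmit(child.sample_id, site)

    for founder in founders:
        for _ in range(config.n_founder_het):
            chrom, pos = positions[cursor]
            site = (chrom, pos, str(refs[cursor]), str(alts[cursor]))
            cursor += 1
            transmit(founder.sample_id, site)

    for _ in range(config.n_shared_ancestral_snvs):
        chrom, pos = positions[cursor]
        ref, alt = str(refs[cursor]), str(alts[cursor])
        cursor += 1
        for s in pedigree:
            rows.append((chrom, pos, ref, alt, s.sample_id, 0.5, "ancestral"))

    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "sample_id", "true_vaf", "origin"])


# ---------------------------------------------------------------------------
# whole-study simulation

@dataclass
class SimResult:
    config: SimConfig
    pedigree: Pedigree
    calls: pd.DataFrame          # long per-site x per-sample observations
    truth: pd.DataFrame          # injected DNMs with true labels
    inherited: pd.DataFrame      # carrier table of background variants
    coverage: pd.DataFrame       # per-sample per-chromosome mean depth

    def truth_for(self, sample_id: str) -> pd.DataFrame:
        return self.truth[self.truth["sample_id"] == sample_id]


def _dnm_lambda(sample: PedigreeSample, config: SimConfig) -> float:
    if sample.sibship_id == "control":
        return config.lambda_control
    if sample.generation == "F2":
        return config.lambda_f2
    if sample.generation == "F1" and sample.diet == "FD":
        return config.lambda_f1
    return 0.0


def _spectrum_for(sample: PedigreeSample, config: SimConfig) -> dict[str, float]:
    if sample.sibship_id == "control" or sample.diet == "FS":
        return config.spectrum_control
    return config.spectrum_fd


def simulate_coverage_profile(pedigree: Pedigree, genome: GenomeModel,
                              depth_mean: float, rng: np.random.Generator,
                              true_sex: dict[str, str]) -> pd.DataFrame:
    """Per-sample per-chromosome mean depth: autosomes at ``depth_mean``;
    males at half depth on X and Y; females at full X and near-zero Y."""
    rows = []
    for s in pedigree:
        sex = true_sex[s.sample_id]
        for chrom in genome.names:
            base = depth_mean
            if chrom == genome.x_name:
                base = depth_mean * (0.5 if sex == "male" else 1.0)
            elif chrom == genome.y_name:
                base = depth_mean * (0.5 if sex == "male" else 0.002)
            depth = max(0.0, rng.normal(base, 0.03 * depth_mean))
            rows.append((s.sample_id, chrom, depth))
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "mean_depth"])


def simulate_study(config: SimConfig) -> SimResult:
    """Run the full generator: pedigree, background variants, injected
    DNMs, read-level observations for every sample at every site, and a
    coverage profile.  A single seeded generator drives every draw."""
    rng = np.random.default_rng(config.seed)
    if not config.genome.repeat_mask:
        # draw the tandem-repeat mask first so variant positions avoid it
        mask_rng = np.random.default_rng(config.seed + 10_007)
        config = dataclasses.replace(config, genome=dataclasses.replace(
            config.genome,
            repeat_mask=random_repeat_mask(config.genome, mask_rng)))
    pedigree = build_study_pedigree(config)

    inherited = simulate_inherited_variants(pedigree, config, rng)
    used = set(zip(inherited["chrom"], inherited["pos"])) if len(inherited) else set()

    truths = []
    for s in pedigree:
        lam = _dnm_lambda(s, config)
        if lam <= 0:
            continue
        t = inject_dnms(s.sample_id, lam, config.p_mismatch,
                        _spectrum_for(s, config), config.genome, rng,
                        exclude_positions=used)
        used.update(zip(t["chrom"], t["pos"]))
        truths.append(t)
    truth = (pd.concat(truths, ignore_index=True) if truths
             else pd.DataFrame(columns=TRUTH_COLUMNS))

    calls = _observe_sites(pedigree, inherited, truth, config, rng)

    # assign true sexes to the unknowns (F2 embryos, controls)
    true_sex = {}
    for s in pedigree:
        true_sex[s.sample_id] = (s.sex if s.sex != "unknown"
                                 else ("male" if rng.random() < 0.5
                                       else "female"))
    coverage = simulate_coverage_profile(pedigree, config.genome,
                                         config.depth_mean, rng, true_sex)
    result = SimResult(config=config, pedigree=pedigree, calls=calls,
                       truth=truth, inherited=inherited, coverage=coverage)
    result.true_sex = true_sex  # type: ignore[attr-defined]
    return result


def build_study_pedigree(config: SimConfig) -> Pedigree:
    return build_pedigree(n_sibships=config.n_sibships,
                          n_f2_per_sibship=config.n_f2_per_sibship,
                          group=config.group, n_controls=config.n_controls)


def _observe_sites(pedigree: Pedigree, inherited: pd.DataFrame,
                   truth: pd.DataFrame, config: SimConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Generate the full site x sample observation matrix.

    Every emitted site is observed in every sample (carriers at their
    true allele fraction, non-carriers at 0), so parental absence of a
    de novo mutation is backed by actual reference-supporting depth.
    """
    sample_ids = [s.sample_id for s in pedigree]
    site_cols = ["chrom", "pos", "ref", "alt"]
    sites = pd.concat([
        inherited[site_cols] if len(inherited) else pd.DataFrame(columns=site_cols),
        truth[site_cols] if len(truth) else pd.DataFrame(columns=site_cols),
    ], ignore_index=True).drop_duplicates().reset_index(drop=True)
    if sites.empty:
        return vcfio.empty_calls()

    n_sites = len(sites)
    n_samples = len(sample_ids)
    sample_index = {sid: i for i, sid in enumerate(sample_ids)}
    site_index = {(c, p, r, a): i for i, (c, p, r, a)
                  in enumerate(sites.itertuples(index=False))}

    vaf = np.zeros((n_sites, n_samples))
    for table in (inherited, truth):
        if not len(table):
            continue
        for row in table.itertuples(index=False):
            i = site_index[(row.chrom, row.pos, row.ref, row.alt)]
            j = sample_index[row.sample_id]
            vaf[i, j] = row.true_vaf

    depth, alt = simulate_reads(vaf.ravel(), config.depth_mean, rng)
    depth = depth.reshape(n_sites, n_samples)
    alt = alt.reshape(n_sites, n_samples)
    qual, mq_ref, mq_alt = draw_site_qualities(n_sites, config, rng)

    long = pd.DataFrame({
        "sample_id": np.repeat(sample_ids, n_sites),
        "chrom": np.tile(sites["chrom"].to_numpy(), n_samples),
        "pos": np.tile(sites["pos"].to_numpy(), n_samples),
        "ref": np.tile(sites["ref"].to_numpy(), n_samples),
        "alt": np.tile(sites["alt"].to_numpy(), n_samples),
        "qual": np.tile(qual, n_samples),
        "total_depth": depth.T.ravel(),
        "ref_depth": (depth - alt).T.ravel(),
        "alt_depth": alt.T.ravel(),
        "mq_ref": np.tile(mq_ref, n_samples),
        "mq_alt": np.tile(mq_alt, n_samples),
    })
    return long


# ---------------------------------------------------------------------------
# SV candidate fabrication

def simulate_sv_candidates(pedigree: Pedigree, genome: GenomeModel,
                           rng: np.random.Generator,
                           n_true_per_f2: int = 3,
                           n_false_per_f2: int = 3,
                           depth_mean: float = 30.0) -> pd.DataFrame:
    """Fabricate SV candidate rows with known depth structure: true
    heterozygous deletions at ~half depth (and duplications at ~1.5x),
    plus false candidates at background depth."""
    rows = []
    lengths = genome.lengths
    for s in pedigree.generation("F2"):
        parents = pedigree.parents_of(s.sample_id)
        for is_true in ([True] * n_true_per_f2 + [False] * n_false_per_f2):
            chrom = genome.names[int(rng.integers(0, len(genome.names)))]
            size = int(rng.integers(100, 1000))
            start = int(rng.integers(0, max(1, lengths[chrom] - size)))
            sv_type = "DEL" if rng.random() < 0.7 else "DUP"
            if is_true:
                factor = 0.45 if sv_type == "DEL" else 1.6
            else:
                factor = 1.0
            region = depth_mean * factor * rng.normal(1.0, 0.02)
            flank = depth_mean * rng.normal(1.0, 0.02)
            rows.append({
                "sample_id": s.sample_id, "chrom": chrom,
                "start": start, "end": start + size, "sv_type": sv_type,
                "region_depth": region, "flank_depth": flank,
                "genome_mean_depth": depth_mean,
                "father_depth": depth_mean * rng.normal(1.0, 0.02),
                "mother_depth": depth_mean * rng.normal(1.0, 0.02),
                "father_id": parents[0].sample_id,
                "mother_id": parents[1].sample_id,
                "is_true_sv": is_true,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture emission

def emit_fixtures(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the study fixtures: multi-sample VCF, PED, genome TSV, BED
    masks, truth/coverage TSVs and a manifest recording the seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = result.config.genome

    paths = {
        "vcf": out / "study.vcf",
        "ped": out / "study.ped",
        "genome": out / "genome.tsv",
        "repeats": out / "repeats.bed",
        "excluded_ends": out / "excluded_ends.bed",
        "truth": out / "truth.tsv",
        "coverage": out / "coverage.tsv",
        "manifest": out / "manifest.json",
    }
    sample_ids = [s.sample_id for s in result.pedigree]
    vcfio.write_vcf(result.calls, genome, paths["vcf"], sample_ids=sample_ids)
    result.pedigree.to_ped(paths["ped"])
    genome.to_tsv(paths["genome"])
    write_bed(genome.repeat_mask, paths["repeats"], chrom_order=genome.names)
    write_bed(genome.excluded_ends, paths["excluded_ends"],
              chrom_order=genome.names)
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    result.coverage.to_csv(paths["coverage"], sep="\t", index=False)
    manifest = {
        "seed": result.config.seed,
        "n_samples": len(sample_ids),
        "n_sites": int(result.calls[["chrom", "pos"]].drop_duplicates().shape[0])
        if len(result.calls) else 0,
        "config": result.config.to_jsonable(),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
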