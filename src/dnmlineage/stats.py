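"""Mutation-rate arithmetic, substitution spectra, hotspot and sex-bias
tests, and the red-blood-cell folate formula.

Substitution spectrum convention
--------------------------------
Point mutations are collapsed onto the six strand-symmetric classes
(``G:C>A:T``, ``A:T>G:C``, ``G:C>T:A``, ``G:C>C:G``, ``A:T>T:A``,
``A:T>C:G``): a substitution and its reverse complement (e.g. ``C>T`` and
``G>A``) are the same biological event observed on opposite strands.

Rate arithmetic
---------------
The expected number of spontaneous de novo mutations per generation is
``rate_per_nt_per_gen x haploid_genome_size x ploidy``; e.g. the mouse
germline rate 5.4e-9 over a 2.7 Gb haploid genome gives ~29 per diploid
generation.  Observed group means divided by that expectation give the
fold increase attributable to the exposure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import GenomeModel

SPECTRUM_CLASSES = ["G:C>A:T", "A:T>G:C", "G:C>T:A",
                    "G:C>C:G", "A:T>T:A", "A:T>C:G"]

#: raw substitution -> strand-collapsed class
SUBSTITUTION_CLASS: dict[tuple[str, str], str] = {
    ("C", "T"): "G:C>A:T", ("G", "A"): "G:C>A:T",
    ("T", "C"): "A:T>G:C", ("A", "G"): "A:T>G:C",
    ("C", "A"): "G:C>T:A", ("G", "T"): "G:C>T:A",
    ("C", "G"): "G:C>C:G", ("G", "C"): "G:C>C:G",
    ("T", "A"): "A:T>T:A", ("A", "T"): "A:T>T:A",
    ("T", "G"): "A:T>C:G", ("A", "C"): "A:T>C:G",
}

#: class -> its two raw (ref, alt) representatives
CLASS_SUBSTITUTIONS: dict[str, list[tuple[str, str]]] = {}
for (_ref, _alt), _cls in SUBSTITUTION_CLASS.items():
    CLASS_SUBSTITUTIONS.setdefault(_cls, []).append((_ref, _alt))


def substitution_class(ref: str, alt: str) -> str:
    """Collapse a single-nucleotide substitution onto its strand-symmetric
    class; raises for non-SNV input."""
    key = (ref.upper(), alt.upper())
    if key not in SUBSTITUTION_CLASS:
        raise ValueError(f"not a single-nucleotide substitution: {ref}>{alt}")
    return SUBSTITUTION_CLASS[key]


# ---------------------------------------------------------------------------
# spectrum tables

@dataclass
class SpectrumTable:
    """Counts and proportions over the six substitution classes."""

    counts: pd.Series
    per_sample: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(SPECTRUM_CLASSES, fill_value=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> pd.Series:
        if self.total == 0:
            return pd.Series(0.0, index=SPECTRUM_CLASSES)
        return self.counts / self.total

    def proportion(self, cls: str = "G:C>A:T") -> float:
        return float(self.proportions[cls])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"count": self.counts,
                             "proportion": self.proportions})


def build_spectrum(records: pd.DataFrame) -> SpectrumTable:
    """Tabulate substitution classes from a table with ``ref``/``alt``
    (and optionally ``sample_id``) columns; non-SNV rows are ignored."""
    if records.empty:
        return SpectrumTable(pd.Series(0, index=SPECTRUM_CLASSES),
                             per_sample=pd.DataFrame(columns=SPECTRUM_CLASSES))
    snv = records[(records["ref"].str.len() == 1)
                  & (records["alt"].str.len() == 1)].copy()
    classes = [substitution_class(r, a)
               for r, a in zip(snv["ref"], snv["alt"])]
    snv["substitution_class"] = classes
    counts = snv["substitution_class"].value_counts()
    per_sample = None
    if "sample_id" in snv.columns:
        per_sample = (snv.groupby("sample_id")["substitution_class"]
                      .value_counts().unstack(fill_value=0)
                      .reindex(columns=SPECTRUM_CLASSES, fill_value=0))
    return SpectrumTable(counts, per_sample=per_sample)


@dataclass
class KSResult:
    statistic: float
    pvalue: float
    extra: dict = field(default_factory=dict)


def compare_spectrum(per_sample_fractions: Sequence[float],
                     per_sample_counts: Sequence[int],
                     reference_proportion: float,
                     rng: np.random.Generator,
                     focal_class: str = "G:C>A:T",
                     n_draws_per_sample: int = 200) -> KSResult:
    """Two-sample KS test of the per-sample focal-class fractions against
    draws from a reference proportion.

    The reference sample is constructed by drawing, for each observed
    sample with ``n_i`` mutations, ``n_draws_per_sample`` binomial
    fractions ``Binomial(n_i, p_ref)/n_i`` — i.e. what the per-sample
    fractions would look like under the reference spectrum at the same
    per-sample mutation counts.
    """
    fractions = np.asarray(per_sample_fractions, dtype=float)
    counts = np.asarray(per_sample_counts, dtype=int)
    if fractions.size < 2:
        raise ValueError("need at least two samples for a KS comparison")
    if fractions.size != counts.size:
        raise ValueError("fractions and counts must align")
    ref_draws = np.concatenate([
        rng.binomial(n, reference_proportion, size=n_draws_per_sample) / n
        for n in counts if n > 0])
    res = sps.ks_2samp(fractions, ref_draws)
    return KSResult(float(res.statistic), float(res.pvalue),
                    extra={"focal_class": focal_class,
                           "reference_proportion": reference_proportion})


def sex_bias_test(male_counts: Sequence[float],
                  female_counts: Sequence[float]) -> KSResult:
    """Two-sample KS test on per-sample DNM counts split by sex."""
    male = np.asarray(male_counts, dtype=float)
    female = np.asarray(female_counts, dtype=float)
    if male.size == 0 or female.size == 0:
        raise ValueError("both sex groups must be non-empty")
    res = sps.ks_2samp(male, female)
    return KSResult(float(res.statistic), float(res.pvalue),
                    extra={"male_median": float(np.median(male)),
                           "female_median": float(np.median(female)),
                           "n_male": int(male.size),
                           "n_female": int(female.size)})


# ---------------------------------------------------------------------------
# rate arithmetic

def expected_dnm_count(rate_per_nt_per_gen: float,
                       haploid_genome_size: float,
                       ploidy: int = 2) -> float:
    """Expected spontaneous DNMs per individual per generation."""
    if rate_per_nt_per_gen < 0 or haploid_genome_size <= 0 or ploidy <= 0:
        raise ValueError("rate must be >= 0; genome size and ploidy > 0")
    return rate_per_nt_per_gen * haploid_genome_size * ploidy


def fold_increase(observed_mean: float, expected_count: float) -> float:
    if expected_count <= 0:
        raise ValueError("expected count must be positive")
    return observed_mean / expected_count


def extrapolate_human(fold: float, baseline_dnms: float = 70.0,
                      deleterious_per_baseline: float = 2.1) -> dict[str, float]:
    """Scale a human spontaneous-DNM baseline by an observed fold change.

    The defaults are the literature round numbers for humans: ~70 DNMs
    per diploid generation, of which ~2.1 are deleterious.
    """
    return {"expected_dnms": fold * baseline_dnms,
            "expected_deleterious": fold * deleterious_per_baseline}


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (report-text
    convention for 'approximately' values)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# genomic windows and hotspot testing

def window_counts(records: pd.DataFrame, genome: GenomeModel,
                  window_size: int = 10_000_000) -> pd.DataFrame:
    """Count mutations in non-overlapping windows tiling each chromosome.

    Windows are 0-based half-open ``[i*W, (i+1)*W)``; a 1-based position
    ``pos`` falls in window ``(pos - 1) // W``.  Terminal windows may be
    shorter than ``W``; their true length is kept so expected counts can
    be exposure-adjusted.
    """
    if window_size <= 0:
        raise ValueError("window size must be positive")
    lengths = genome.lengths
    frames = []
    for chrom, length in genome.chromosomes:
        starts = np.arange(0, length, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                    "end": ends}))
    windows = pd.concat(frames, ignore_index=True)
    windows["length"] = windows["end"] - windows["start"]
    windows["count"] = 0

    if not records.empty:
        for chrom, group in records.groupby("chrom"):
            if chrom not in lengths:
                raise ValueError(f"unknown chromosome {chrom}")
            pos = group["pos"].to_numpy(dtype=np.int64)
            if (pos < 1).any() or (pos > lengths[chrom]).any():
                raise ValueError(f"position outside {chrom}")
            idx = (pos - 1) // window_size
            sel = windows["chrom"] == chrom
            counts = np.bincount(idx, minlength=int(sel.sum()))
            windows.loc[sel, "count"] += counts
    return windows


@dataclass
class HotspotTestResult:
    lambda_per_bp: float
    mean_count: float
    dispersion_statistic: float
    dispersion_pvalue: float
    dispersion_direction: str  # over / under / none
    gof_statistic: float | None
    gof_pvalue: float | None
    reject_poisson: bool
    hotspots: pd.DataFrame
    alpha: float

    def summary(self) -> dict:
        return {
            "lambda_per_bp": self.lambda_per_bp,
            "mean_count": self.mean_count,
            "dispersion_statistic": self.dispersion_statistic,
            "dispersion_pvalue": self.dispersion_pvalue,
            "dispersion_direction": self.dispersion_direction,
            "gof_statistic": self.gof_statistic,
            "gof_pvalue": self.gof_pvalue,
            "reject_poisson": self.reject_poisson,
            "n_hotspots": int(len(self.hotspots)),
            "alpha": self.alpha,
        }


def poisson_hotspot_test(windows: pd.DataFrame, alpha: float = 0.05,
                         hotspot_threshold: int = 14) -> HotspotTestResult:
    """Test window counts against a homogeneous Poisson model and flag
    high-count windows.

    Dispersion test: with per-window exposures ``w_i`` (window lengths)
    and rate ``lambda = sum(c_i)/sum(w_i)``, the Pearson statistic
    ``sum((c_i - lambda*w_i)^2 / (lambda*w_i))`` is approximately
    chi-square with ``n - 1`` degrees of freedom under the Poisson null;
    the reported p-value is two-sided (over- and under-dispersion).

    Goodness of fit: a chi-square on the histogram of counts over the
    equal-length windows, bins merged to expected counts >= 5, degrees
    of freedom reduced by one for the estimated mean.

    Windows with ``count >= hotspot_threshold`` are returned as hotspots.
    """
    if windows.empty:
        raise ValueError("no windows to test")
    if len(windows) < 10:
        raise ValueError("need at least 10 windows for the Poisson test")
    counts = windows["count"].to_numpy(dtype=float)
    exposures = windows["length"].to_numpy(dtype=float)
    lam_bp = counts.sum() / exposures.sum()
    expected = lam_bp * exposures
    n = len(counts)

    if expected.min() <= 0:
        raise ValueError("zero expected count in a window")
    if counts.sum() == 0:
        stat, pval, direction = 0.0, 1.0, "under"
    else:
        stat = float(((counts - expected) ** 2 / expected).sum())
        df = n - 1
        upper = sps.chi2.sf(stat, df)
        lower = sps.chi2.cdf(stat, df)
        pval = float(min(1.0, 2 * min(upper, lower)))
        direction = "over" if stat > df else "under"

    gof_stat = gof_p = None
    full = counts[exposures == exposures.max()]
    if full.size >= 10 and full.sum() > 0:
        gof_stat, gof_p = _binned_poisson_gof(full)

    reject = pval < alpha
    hotspots = windows[windows["count"] >= hotspot_threshold].copy()
    return HotspotTestResult(
        lambda_per_bp=float(lam_bp), mean_count=float(counts.mean()),
        dispersion_statistic=stat, dispersion_pvalue=pval,
        dispersion_direction=direction if pval < 1.0 else "none",
        gof_statistic=gof_stat, gof_pvalue=gof_p,
        reject_poisson=bool(reject), hotspots=hotspots, alpha=alpha)


def _binned_poisson_gof(counts: np.ndarray,
                        min_expected: float = 5.0) -> tuple[float, float]:
    """Chi-square goodness of fit of integer counts to Poisson(mean),
    with tail bins merged up to ``min_expected``."""
    lam = counts.mean()
    kmax = int(counts.max())
    ks = np.arange(kmax + 1)
    probs = sps.poisson.pmf(ks, lam)
    probs = np.append(probs, max(1.0 - probs.sum(), 0.0))  # tail bin
    observed = np.append(np.bincount(counts.astype(int), minlength=kmax + 1),
                         0.0)
    expected = probs * counts.size
    # merge adjacent bins until each expected >= min_expected
    obs_m, exp_m = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            obs_m.append(o_acc)
            exp_m.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0 and exp_m:
        obs_m[-1] += o_acc
        exp_m[-1] += e_acc
    if len(exp_m) < 3:
        return float("nan"), float("nan")
    obs_arr, exp_arr = np.array(obs_m), np.array(exp_m)
    exp_arr *= obs_arr.sum() / exp_arr.sum()
    stat = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    df = len(exp_arr) - 2  # one for totals, one for the estimated mean
    return stat, float(sps.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# blood chemistry

def rbc_folate(fa_whole_blood: float, fa_plasma: float,
               hct_pct: float) -> float:
    """Red-blood-cell folate from whole-blood folate, plasma folate and
    the cell fraction (haematocrit, percent):

        FA_rbc = FA_whole / HCT * 100 - FA_plasma * (100 - HCT) / HCT

    A negative result is physically impossible and triggers a warning.
    """
    if hct_pct <= 0 or hct_pct > 100:
        raise ValueError("haematocrit must be in (0, 100] percent")
    if fa_whole_blood < 0 or fa_plasma < 0:
        raise ValueError("folate concentrations must be non-negative")
    value = fa_whole_blood / hct_pct * 100 - fa_plasma * (100 - hct_pct) / hct_pct
    if value < 0:
        warnings.warn("negative red-cell folate: inputs are inconsistent",
                      UserWarning, stacklevel=2)
    return value
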