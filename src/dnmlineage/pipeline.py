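"""End-to-end run: simulate -> filter -> call -> classify -> stats ->
svscreen, with a JSON report and a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, vcfio
from .alleleratio import GenotypeClassRule, classify_table, timing_summary
from .calling import (PresenceRule, call_dnms, count_dnms_by_sample,
                      infer_sexes, remove_shared_from_calls)
from .filters import FilterThresholds, filter_variants
from .genome import MOUSE_GENOME_SIZE, GenomeModel
from .pedigree import Pedigree
from .simulate import SimConfig, emit_fixtures, simulate_study
from .stats import (build_spectrum, compare_spectrum, expected_dnm_count,
                    extrapolate_human, fold_increase, poisson_hotspot_test,
                    round_half_up, sex_bias_test, window_counts)
from .svscreen import filter_sv_candidates, flag_de_novo_svs, normalize_depths

log = logging.getLogger("dnmlineage")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a reproducible run needs.  Either a simulation config
    or explicit input paths must be given."""

    out_dir: str | Path = "run"
    seed: int = 0
    sim: SimConfig | None = None
    vcf: str | None = None
    ped: str | None = None
    genome_tsv: str | None = None
    repeat_bed: str | None = None
    excluded_bed: str | None = None
    coverage_tsv: str | None = None
    sv_candidates: str | None = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    presence: PresenceRule = field(default_factory=PresenceRule)
    genotype_rule: GenotypeClassRule = field(default_factory=GenotypeClassRule)
    window_size: int = 10_000_000
    hotspot_threshold: int = 14
    spontaneous_rate: float = 5.4e-9
    reference_genome_size: float = MOUSE_GENOME_SIZE
    ploidy: int = 2
    control_focal_proportion: float = 0.53  # normal-diet G:C>A:T share

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "sim" in kwargs and kwargs["sim"] is not None:
            kwargs["sim"] = SimConfig(**kwargs["sim"])
        for key, klass in (("thresholds", FilterThresholds),
                           ("presence", PresenceRule),
                           ("genotype_rule", GenotypeClassRule)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        cfg = cls(**kwargs)
        if cfg.sim is not None:
            cfg.sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, writing artifacts under ``config.out_dir``;
    returns the report dictionary (also written as ``report.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "version": __version__}
    inputs: dict[str, str] = {}

    # ---- stage: simulate (optional) -----------------------------------
    truth = None
    true_sex = None
    try:
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            result = simulate_study(sim)
            paths = emit_fixtures(result, out / "sim")
            truth = result.truth
            true_sex = getattr(result, "true_sex", None)
            config = dataclasses.replace(
                config,
                vcf=str(paths["vcf"]), ped=str(paths["ped"]),
                genome_tsv=str(paths["genome"]),
                repeat_bed=str(paths["repeats"]),
                excluded_bed=str(paths["excluded_ends"]),
                coverage_tsv=str(paths["coverage"]))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", exc) from exc

    # ---- stage: load ---------------------------------------------------
    try:
        for name in ("vcf", "ped", "genome_tsv"):
            value = getattr(config, name)
            if value is None:
                raise FileNotFoundError(f"missing required input '{name}'")
            if not Path(value).exists():
                raise FileNotFoundError(f"input {name} not found: {value}")
            inputs[name] = _sha256(Path(value))
        genome = GenomeModel.from_tsv(config.genome_tsv,
                                      repeat_bed=config.repeat_bed,
                                      excluded_bed=config.excluded_bed)
        pedigree = Pedigree.from_ped(config.ped)
        calls = vcfio.read_vcf(config.vcf)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("load", exc) from exc

    # ---- stage: filter -------------------------------------------------
    try:
        kept, rejected = filter_variants(calls, mask=genome.repeat_mask,
                                         thresholds=config.thresholds)
        kept.to_csv(out / "filtered.tsv", sep="\t", index=False)
        rejected.to_csv(out / "rejected.tsv", sep="\t", index=False)
        report["filter"] = {
            "n_input": int(len(calls)), "n_kept": int(len(kept)),
            "n_rejected": int(len(rejected)),
            "rejections_by_rule": rejected["reason"].value_counts().to_dict()
            if len(rejected) else {}}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("filter", exc) from exc

    # ---- stage: call ---------------------------------------------------
    try:
        qualified, removed_shared = remove_shared_from_calls(
            kept, pedigree, config.presence)
        focal = pedigree.dnm_focal_ids()
        dnm_frames = [call_dnms(sid, pedigree, qualified, raw=calls,
                                rule=config.presence) for sid in focal]
        dnms = (pd.concat(dnm_frames, ignore_index=True) if dnm_frames
                else pd.DataFrame())
        dnms.to_csv(out / "dnms.tsv", sep="\t", index=False)
        report["call"] = {"n_dnms": int(len(dnms)),
                          "n_shared_removed": int(len(removed_shared))}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("call", exc) from exc

    # ---- stage: classify ----------------------------------------------
    try:
        classified = classify_table(dnms, config.genotype_rule) \
            if len(dnms) else dnms
        classified.to_csv(out / "classified.tsv", sep="\t", index=False)
        report["timing"] = timing_summary(classified)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("classify", exc) from exc

    # ---- stage: stats --------------------------------------------------
    try:
        report["stats"] = _stats_bundle(classified, pedigree, genome, config,
                                        out, true_sex=true_sex)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("stats", exc) from exc

    # ---- stage: svscreen (optional) ------------------------------------
    try:
        if config.sv_candidates and Path(config.sv_candidates).exists():
            candidates = pd.read_csv(config.sv_candidates, sep="\t")
            sibship_by_sample = {s.sample_id: s.sibship_id or "NA"
                                 for s in pedigree}
            normalized = normalize_depths(candidates, sibship_by_sample)
            kept_svs = filter_sv_candidates(normalized, genome.excluded_ends)
            flagged = flag_de_novo_svs(kept_svs)
            flagged.to_csv(out / "svs_kept.tsv", sep="\t", index=False)
            report["svscreen"] = {
                "n_candidates": int(len(candidates)),
                "n_kept": int(len(kept_svs)),
                "n_flagged_de_novo": int(flagged["de_novo_flag"].sum())
                if len(flagged) else 0}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("svscreen", exc) from exc

    # ---- recall against truth (simulation runs only) -------------------
    if truth is not None and len(truth):
        truth = truth[truth["sample_id"].isin(set(pedigree.dnm_focal_ids()))]
        merged = truth.merge(
            dnms, on=["sample_id", "chrom", "pos", "ref", "alt"],
            how="left", indicator=True)
        report["truth_recall"] = {
            "n_injected": int(len(truth)),
            "n_recovered": int((merged["_merge"] == "both").sum())}

    report_json = json.dumps(report, indent=2, sort_keys=True, default=_json_default)
    (out / "report.json").write_text(report_json)
    (out / "report.md").write_text(render_report(report))
    manifest = {"seed": config.seed, "version": __version__,
                "inputs": inputs,
                "report_sha256": hashlib.sha256(
                    report_json.encode()).hexdigest()}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _stats_bundle(classified: pd.DataFrame, pedigree: Pedigree,
                  genome: GenomeModel, config: RunConfig, out: Path,
                  true_sex: dict | None = None) -> dict:
    bundle: dict = {}
    expected = expected_dnm_count(config.spontaneous_rate,
                                  config.reference_genome_size, config.ploidy)
    counts = count_dnms_by_sample(classified, pedigree)
    bundle["expected_spontaneous"] = expected
    bundle["per_sample_counts"] = counts["per_sample"].to_dict()
    bundle["per_sibship_f2_mean"] = counts["per_sibship_f2_mean"]
    bundle["f2_mean"] = counts["f2_mean"]
    bundle["fold_increase"] = (fold_increase(counts["f2_mean"], expected)
                               if counts["f2_mean"] > 0 else 0.0)
    bundle["human_extrapolation"] = extrapolate_human(bundle["fold_increase"])

    f2_ids = [s.sample_id for s in pedigree.generation("F2")]
    f2_dnms = classified[classified["sample_id"].isin(f2_ids)] \
        if len(classified) else classified
    spectrum = build_spectrum(f2_dnms) if len(f2_dnms) else build_spectrum(
        pd.DataFrame(columns=["sample_id", "ref", "alt"]))
    spectrum.to_frame().to_csv(out / "spectrum.tsv", sep="\t")
    bundle["spectrum"] = spectrum.to_frame()["proportion"].to_dict()
    bundle["spectrum_total"] = spectrum.total

    rng = np.random.default_rng(config.seed + 20_011)
    if spectrum.per_sample is not None and len(spectrum.per_sample) >= 2:
        per_sample_counts = spectrum.per_sample.sum(axis=1)
        ok = per_sample_counts > 0
        fractions = (spectrum.per_sample.loc[ok, "G:C>A:T"]
                     / per_sample_counts[ok])
        ks = compare_spectrum(fractions.to_numpy(),
                              per_sample_counts[ok].to_numpy(dtype=int),
                              config.control_focal_proportion, rng)
        bundle["spectrum_vs_control"] = {
            "statistic": ks.statistic, "pvalue": ks.pvalue, **ks.extra}

    if len(f2_dnms):
        windows = window_counts(f2_dnms, genome, config.window_size)
        windows.to_csv(out / "windows.tsv", sep="\t", index=False)
        if len(windows) >= 10:
            hotspot = poisson_hotspot_test(
                windows, hotspot_threshold=config.hotspot_threshold)
            bundle["hotspot"] = hotspot.summary()

    # sex split: inferred from coverage when available, else pedigree sex
    sexes = None
    if config.coverage_tsv and Path(config.coverage_tsv).exists():
        coverage = pd.read_csv(config.coverage_tsv, sep="\t")
        sexes = infer_sexes(coverage, genome)
        bundle["inferred_sex"] = sexes.to_dict()
        if true_sex is not None:
            agree = sum(sexes.get(sid) == sx for sid, sx in true_sex.items())
            bundle["sex_inference_agreement"] = agree / len(true_sex)
    sex_map = (sexes.to_dict() if sexes is not None
               else {s.sample_id: s.sex for s in pedigree})
    by_sex = count_dnms_by_sample(classified, pedigree,
                                  sex_by_sample=sex_map)["f2_counts_by_sex"]
    bundle["f2_counts_by_sex"] = by_sex
    if by_sex.get("male") and by_sex.get("female"):
        ks = sex_bias_test(by_sex["male"], by_sex["female"])
        bundle["sex_bias"] = {"statistic": ks.statistic,
                              "pvalue": ks.pvalue, **ks.extra}
    return bundle


def render_report(report: dict) -> str:
    """Human-readable markdown summary; 'approximately' values show raw
    and rounded forms."""
    lines = ["# dnmlineage run report", ""]
    lines.append(f"Seed: {report.get('seed')}  |  version "
                 f"{report.get('version')}")
    stats = report.get("stats", {})
    timing = report.get("timing", {})
    total = timing.get("total", 0)

    lines.append("\n## De novo mutations\n")
    if total == 0 and not stats.get("per_sample_counts"):
        lines.append("Zero DNMs called; downstream tests skipped.")
    if stats:
        exp = stats.get("expected_spontaneous")
        fold = stats.get("fold_increase")
        lines.append(f"- F2 mean DNM count: {stats.get('f2_mean', 0):.2f}")
        if exp is not None:
            lines.append(f"- Expected spontaneous count: {exp:.2f} "
                         f"(approximately {round_half_up(exp)})")
        if fold:
            lines.append(f"- Fold increase over spontaneous: {fold:.3f} "
                         f"(approximately {round_half_up(fold)}x)")
        for sib, mean in stats.get("per_sibship_f2_mean", {}).items():
            lines.append(f"- Sibship {sib}: mean {mean:.1f} DNMs per F2")
        human = stats.get("human_extrapolation")
        if human and fold:
            lines.append(
                f"- Human-scale extrapolation: {human['expected_dnms']:.1f} "
                f"DNMs (approximately "
                f"{round_half_up(human['expected_dnms'])}), "
                f"{human['expected_deleterious']:.2f} deleterious "
                f"(approximately "
                f"{round_half_up(human['expected_deleterious'])})")

    lines.append("\n## Mutation timing classes\n")
    if total:
        for cls, n in timing.get("counts", {}).items():
            frac = timing["fractions"].get(cls, 0.0)
            lines.append(f"- {cls}: {n} ({100 * frac:.1f}%)")
    else:
        lines.append("No classified DNMs.")

    lines.append("\n## Substitution spectrum\n")
    spectrum = stats.get("spectrum", {})
    if stats.get("spectrum_total"):
        for cls, p in spectrum.items():
            lines.append(f"- {cls}: {100 * p:.1f}%")
        lines.append(f"- (six classes sum to "
                     f"{100 * sum(spectrum.values()):.1f}%)")
        ks = stats.get("spectrum_vs_control")
        if ks:
            lines.append(f"- KS vs control G:C>A:T share: D={ks['statistic']:.3f}, "
                         f"p={ks['pvalue']:.3g}")
    else:
        lines.append("No spectrum (zero SNVs); test skipped.")

    lines.append("\n## Hotspots\n")
    hotspot = stats.get("hotspot")
    if hotspot:
        lines.append(f"- Dispersion test p={hotspot['dispersion_pvalue']:.3g} "
                     f"({hotspot['dispersion_direction']}-dispersed); "
                     f"Poisson rejected: {hotspot['reject_poisson']}")
        lines.append(f"- Windows at or above the hotspot threshold: "
                     f"{hotspot['n_hotspots']}")
    else:
        lines.append("Hotspot test skipped.")

    lines.append("\n## Sex bias\n")
    sex = stats.get("sex_bias")
    if sex:
        lines.append(f"- KS D={sex['statistic']:.3f}, p={sex['pvalue']:.3g} "
                     f"(male median {sex['male_median']:.1f}, female median "
                     f"{sex['female_median']:.1f})")
    else:
        lines.append("Sex-bias test skipped (need both sexes).")

    if "svscreen" in report:
        sv = report["svscreen"]
        lines.append("\n## Structural variants\n")
        lines.append(f"- Candidates: {sv['n_candidates']}, kept "
                     f"{sv['n_kept']}, flagged de novo "
                     f"{sv['n_flagged_de_novo']}")
    lines.append("")
    return "\n".join(lines)
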