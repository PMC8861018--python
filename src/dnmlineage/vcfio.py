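"""Multi-sample VCF round-trip built on :mod:`pysam`.

The package's in-memory variant container is a long-format pandas
DataFrame with one row per site x sample observation:

``sample_id, chrom, pos, ref, alt, qual, total_depth, ref_depth,
alt_depth, mq_ref, mq_alt``

Positions are 1-based.  On disk the same information is a VCF 4.2 with
per-sample ``GT:DP:AD`` and site-level ``INFO/MQREF`` and ``INFO/MQALT``
(mean mapping quality of reference- and alternate-supporting reads).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genome import GenomeModel

CALL_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "qual",
                "total_depth", "ref_depth", "alt_depth", "mq_ref", "mq_alt"]

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]


def _build_header(genome: GenomeModel, sample_ids: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in genome.chromosomes:
        header.contigs.add(name, length=length)
    header.info.add("MQREF", number=1, type="Float",
                    description="Mean mapping quality of reads supporting REF")
    header.info.add("MQALT", number=1, type="Float",
                    description="Mean mapping quality of reads supporting ALT")
    header.formats.add("GT", number=1, type="String", description="Genotype")
    header.formats.add("DP", number=1, type="Integer", description="Read depth")
    header.formats.add("AD", number="R", type="Integer",
                       description="Allelic depths (ref, alt)")
    for sid in sample_ids:
        header.add_sample(sid)
    return header


def write_vcf(calls: pd.DataFrame, genome: GenomeModel, path: str | Path,
              sample_ids: list[str] | None = None) -> None:
    """Write long-format calls to a multi-sample VCF.

    Site-level fields (qual, mapping qualities) must agree across the
    samples of a site; the first record of each site is used.  Samples
    with ``alt_depth > 0`` are written as ``0/1``, others as ``0/0``.
    """
    if sample_ids is None:
        sample_ids = sorted(calls["sample_id"].unique()) if len(calls) else []
    header = _build_header(genome, sample_ids)
    chrom_rank = {name: i for i, (name, _) in enumerate(genome.chromosomes)}

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        if calls.empty:
            return
        sites = calls.sort_values(
            ["chrom", "pos"],
            key=lambda s: s.map(chrom_rank) if s.name == "chrom" else s,
        )
        for (chrom, pos, ref, alt), group in sites.groupby(
                VARIANT_KEY, sort=False):
            first = group.iloc[0]
            rec = vcf.new_record(
                contig=chrom, start=int(pos) - 1, alleles=(ref, alt),
                qual=float(first["qual"]))
            rec.info["MQREF"] = float(first["mq_ref"])
            rec.info["MQALT"] = float(first["mq_alt"])
            by_sample = group.set_index("sample_id")
            for sid in sample_ids:
                sample = rec.samples[sid]
                if sid in by_sample.index:
                    row = by_sample.loc[sid]
                    dp = int(row["total_depth"])
                    ad_alt = int(row["alt_depth"])
                    sample["GT"] = (0, 1) if ad_alt > 0 else (0, 0)
                    sample["DP"] = dp
                    sample["AD"] = (dp - ad_alt, ad_alt)
                else:
                    sample["GT"] = (None, None)
            vcf.write(rec)


def read_vcf(path: str | Path, keep_missing: bool = False) -> pd.DataFrame:
    """Read a multi-sample VCF into the long-format call table.

    By default only samples with a called genotype at a site are
    returned; ``keep_missing`` also emits rows for ``./.`` genotypes
    (with zero depths).
    """
    rows: list[tuple] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else "."
            qual = float(rec.qual) if rec.qual is not None else 0.0
            mq_ref = float(rec.info.get("MQREF", 0.0))
            mq_alt = float(rec.info.get("MQALT", 0.0))
            for sid, sample in rec.samples.items():
                gt = sample.get("GT")
                missing = gt is None or all(a is None for a in gt)
                if missing and not keep_missing:
                    continue
                dp = sample.get("DP")
                ad = sample.get("AD")
                dp = 0 if dp is None else int(dp)
                ad_alt = 0 if not ad or ad[1] is None else int(ad[1])
                rows.append((sid, rec.contig, rec.pos, rec.ref, alt, qual,
                             dp, dp - ad_alt, ad_alt, mq_ref, mq_alt))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def empty_calls() -> pd.DataFrame:
    return pd.DataFrame(columns=CALL_COLUMNS).astype(
        {"pos": np.int64, "total_depth": np.int64,
         "ref_depth": np.int64, "alt_depth": np.int64})
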