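"""Genome model: chromosome table, interval masks and coordinate conventions.

Variant positions throughout the package are 1-based (VCF convention);
all interval sets (repeat masks, excluded chromosome ends, window tilings)
are 0-based half-open (BED convention).  A variant at 1-based position
``pos`` overlaps an interval ``[start, end)`` iff ``start <= pos - 1 < end``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

IntervalMap = dict[str, list[tuple[int, int]]]

# mm10 chromosome lengths scaled 1:100 — a desk-scale stand-in for the
# ~2.7 Gb mouse genome so uniform position draws and window statistics run
# in seconds.  Rate arithmetic never uses these lengths implicitly; genome
# size is always an explicit parameter.
_MOUSE_CHROM_LENGTHS_1_100 = {
    "chr1": 1_954_720, "chr2": 1_821_132, "chr3": 1_600_397,
    "chr4": 1_565_081, "chr5": 1_518_347, "chr6": 1_497_365,
    "chr7": 1_454_415, "chr8": 1_294_012, "chr9": 1_245_951,
    "chr10": 1_306_950, "chr11": 1_220_825, "chr12": 1_201_290,
    "chr13": 1_204_216, "chr14": 1_249_022, "chr15": 1_040_437,
    "chr16": 982_078, "chr17": 949_873, "chr18": 907_026,
    "chr19": 614_316, "chrX": 1_710_313, "chrY": 917_447,
}

MOUSE_GENOME_SIZE = 2.7e9  #: haploid mouse genome size in bp
HUMAN_GENOME_SIZE = 3.2e9  #: haploid human genome size in bp


@dataclass
class GenomeModel:
    """Ordered chromosome table plus interval masks.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    x_name, y_name
        Names of the sex chromosomes; every other chromosome is an autosome.
    repeat_mask
        Tandem-repeat intervals per chromosome, 0-based half-open.
    excluded_ends
        Centromere/telomere-proximal intervals per chromosome, 0-based
        half-open; used by the SV screen.
    """

    chromosomes: list[tuple[str, int]]
    x_name: str = "chrX"
    y_name: str = "chrY"
    repeat_mask: IntervalMap = field(default_factory=dict)
    excluded_ends: IntervalMap = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def autosome_names(self) -> list[str]:
        return [n for n in self.names if n not in (self.x_name, self.y_name)]

    def total_length(self, include_sex: bool = True) -> int:
        names = self.names if include_sex else self.autosome_names
        lengths = self.lengths
        return sum(lengths[n] for n in names)

    def validate(self) -> None:
        lengths = self.lengths
        if not self.chromosomes:
            raise ValueError("genome model needs at least one chromosome")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for label, intervals in (("repeat_mask", self.repeat_mask),
                                 ("excluded_ends", self.excluded_ends)):
            for chrom, ivs in intervals.items():
                if chrom not in lengths:
                    raise ValueError(f"{label}: unknown chromosome {chrom}")
                for start, end in ivs:
                    if not (0 <= start < end <= lengths[chrom]):
                        raise ValueError(
                            f"{label}: interval [{start},{end}) outside "
                            f"{chrom} (length {lengths[chrom]})")

    # -- constructors ----------------------------------------------------
    @classmethod
    def mouse_desk_scale(cls, excluded_end_fraction: float = 0.005) -> "GenomeModel":
        """19 autosomes + X + Y at 1:100 mouse scale (~27 Mb total).

        ``excluded_end_fraction`` of each chromosome end is marked as a
        centromere/telomere-proximal excluded region.
        """
        chroms = list(_MOUSE_CHROM_LENGTHS_1_100.items())
        excluded: IntervalMap = {}
        for name, length in chroms:
            pad = max(1, int(round(length * excluded_end_fraction)))
            excluded[name] = [(0, pad), (length - pad, length)]
        return cls(chromosomes=chroms, excluded_ends=excluded)

    # -- interval utilities ----------------------------------------------
    def mask_trees(self, which: str = "repeat_mask") -> dict[str, IntervalTree]:
        intervals = getattr(self, which)
        return {chrom: IntervalTree.from_tuples(ivs)
                for chrom, ivs in intervals.items() if ivs}

    def unmasked_intervals(self) -> list[tuple[str, int, int]]:
        """Complement of the repeat mask, as (chrom, start, end) triples."""
        out: list[tuple[str, int, int]] = []
        for name, length in self.chromosomes:
            cursor = 0
            for start, end in sorted(self.repeat_mask.get(name, [])):
                if start > cursor:
                    out.append((name, cursor, start))
                cursor = max(cursor, end)
            if cursor < length:
                out.append((name, cursor, length))
        return out

    # -- serialisation ---------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        rows = [{"chrom": n, "length": l,
                 "role": ("X" if n == self.x_name else
                          "Y" if n == self.y_name else "autosome")}
                for n, l in self.chromosomes]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 repeat_bed: str | Path | None = None,
                 excluded_bed: str | Path | None = None) -> "GenomeModel":
        df = pd.read_csv(path, sep="\t")
        chroms = list(zip(df["chrom"], df["length"].astype(int)))
        x = df.loc[df["role"] == "X", "chrom"]
        y = df.loc[df["role"] == "Y", "chrom"]
        model = cls(
            chromosomes=chroms,
            x_name=x.iloc[0] if len(x) else "chrX",
            y_name=y.iloc[0] if len(y) else "chrY",
        )
        if repeat_bed is not None:
            model.repeat_mask = read_bed(repeat_bed)
        if excluded_bed is not None:
            model.excluded_ends = read_bed(excluded_bed)
        model.validate()
        return model


def read_bed(path: str | Path) -> IntervalMap:
    """Read a 3+ column BED file into 0-based half-open intervals."""
    out: IntervalMap = {}
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    if df.empty:
        return out
    for chrom, start, end in df.itertuples(index=False):
        out.setdefault(chrom, []).append((int(start), int(end)))
    return out


def write_bed(intervals: IntervalMap, path: str | Path,
              chrom_order: Sequence[str] | None = None) -> None:
    rows = []
    order = chrom_order or sorted(intervals)
    for chrom in order:
        for start, end in sorted(intervals.get(chrom, [])):
            rows.append((chrom, start, end))
    pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
        path, sep="\t", index=False, header=False)


def random_repeat_mask(genome: GenomeModel, rng: np.random.Generator,
                       n_per_chrom: int = 3,
                       interval_length: int = 2_000) -> IntervalMap:
    """Draw disjoint fixed-length mask intervals on each chromosome."""
    mask: IntervalMap = {}
    for name, length in genome.chromosomes:
        if length <= interval_length * (n_per_chrom + 1):
            continue
        starts = np.sort(rng.choice(length - interval_length,
                                    size=n_per_chrom, replace=False))
        ivs: list[tuple[int, int]] = []
        for s in starts:
            s = int(s)
            if ivs and s < ivs[-1][1]:  # merge overlaps
                ivs[-1] = (ivs[-1][0], s + interval_length)
            else:
                ivs.append((s, s + interval_length))
        mask[name] = ivs
    return mask


def sample_positions(genome: GenomeModel, n: int, rng: np.random.Generator,
                     exclude: Iterable[tuple[str, int]] = (),
                     ) -> list[tuple[str, int]]:
    """Sample ``n`` distinct 1-based positions uniformly over the unmasked
    genome, avoiding ``exclude`` (collisions are re-drawn)."""
    segments = genome.unmasked_intervals()
    seg_lengths = np.array([end - start for _, start, end in segments],
                           dtype=np.int64)
    total = int(seg_lengths.sum())
    if total < n:
        raise ValueError(
            f"unmasked genome ({total} bp) smaller than requested "
            f"number of positions ({n})")
    cum = np.concatenate([[0], np.cumsum(seg_lengths)])
    taken = set(exclude)
    out: list[tuple[str, int]] = []
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 1000:
            raise RuntimeError("position sampling failed to converge")
        draws = rng.integers(0, total, size=(n - len(out)) * 2 + 8)
        idx = np.searchsorted(cum, draws, side="right") - 1
        for offset, seg_i in zip(draws, idx):
            chrom, start, _ = segments[seg_i]
            pos = int(start + (offset - cum[seg_i]) + 1)  # 1-based
            key = (chrom, pos)
            if key in taken:
                continue
            taken.add(key)
            out.append(key)
            if len(out) == n:
                break
    return out
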