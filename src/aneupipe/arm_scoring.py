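"""Chromosome-arm-level copy-number calling and the aneuploidy score.

A tumor's segmented absolute copy-number profile (from an ABSOLUTE-style
caller) is reduced to one copy number per chromosome arm by taking the
weighted median of segment copy numbers, weighted by the length of each
segment's overlap with the arm.  Each arm is then called amplified (+1),
neutral (0) or deleted (-1) by comparing the arm copy number with the
sample ploidy rounded to the nearest integer.  The aneuploidy score (AS)
of a sample is the number of altered arms.

Only autosomes contribute to the score: sex-chromosome segments are
accepted on input but excluded from arm calling, and acrocentric p-arms
are counted like any other arm.  The arm universe is therefore 44
autosomal arms by default, with a configurable exclusion list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY", "23", "24"})

# Autosome lengths and approximate centromere midpoints (bp, GRCh38 scale).
# Used by default_genome(); any other coordinate frame can be supplied as a
# TSV via GenomeModel.from_tsv.
_DEFAULT_AUTOSOMES: tuple[tuple[str, int, int], ...] = (
    ("1", 248_956_422, 123_400_000),
    ("2", 242_193_529, 93_900_000),
    ("3", 198_295_559, 90_900_000),
    ("4", 190_214_555, 50_000_000),
    ("5", 181_538_259, 48_800_000),
    ("6", 170_805_979, 59_800_000),
    ("7", 159_345_973, 60_100_000),
    ("8", 145_138_636, 45_200_000),
    ("9", 138_394_717, 43_000_000),
    ("10", 133_797_422, 39_800_000),
    ("11", 135_086_622, 53_400_000),
    ("12", 133_275_309, 35_500_000),
    ("13", 114_364_328, 17_700_000),
    ("14", 107_043_718, 17_200_000),
    ("15", 101_991_189, 19_000_000),
    ("16", 90_338_345, 36_800_000),
    ("17", 83_257_441, 25_100_000),
    ("18", 80_373_285, 18_500_000),
    ("19", 58_617_616, 26_200_000),
    ("20", 64_444_167, 28_100_000),
    ("21", 46_709_983, 12_000_000),
    ("22", 50_818_468, 15_000_000),
)


class FormatError(ValueError):
    """Raised when an input file or in-memory table violates its contract."""


@dataclass(frozen=True)
class Arm:
    """One chromosome arm: a half-open-free, 1-based inclusive interval."""

    name: str          # e.g. "8p"
    chromosome: str    # e.g. "8"
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeModel:
    """Coordinate frame for arm calls: per-chromosome length and centromere.

    The p arm spans [1, centromere] and the q arm [centromere + 1, length],
    so the two arms tile the chromosome without overlap.
    """

    chromosomes: dict[str, tuple[int, int]]  # name -> (length, centromere)
    exclude_arms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name, (length, cen) in self.chromosomes.items():
            if not (0 < cen < length):
                raise ValueError(
                    f"chromosome {name}: centromere {cen} must lie strictly "
                    f"inside (0, {length})"
                )

    @property
    def arms(self) -> list[Arm]:
        out: list[Arm] = []
        for name, (length, cen) in self.chromosomes.items():
            for arm_name, start, end in (
                (f"{name}p", 1, cen),
                (f"{name}q", cen + 1, length),
            ):
                if arm_name not in self.exclude_arms:
                    out.append(Arm(arm_name, name, start, end))
        return out

    @property
    def arm_names(self) -> list[str]:
        return [a.name for a in self.arms]

    def arm_of(self, chromosome: str, pos: int) -> str:
        length, cen = self.chromosomes[chromosome]
        if not (1 <= pos <= length):
            raise ValueError(f"position {pos} outside chromosome {chromosome}")
        return f"{chromosome}p" if pos <= cen else f"{chromosome}q"

    @classmethod
    def from_tsv(cls, path) -> "GenomeModel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"chrom", "length", "centromere"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"genome model file must have columns {sorted(required)}"
            )
        return cls(
            {
                str(r.chrom): (int(r.length), int(r.centromere))
                for r in df.itertuples()
            }
        )

    def to_tsv(self, path) -> None:
        rows = [
            {"chrom": c, "length": l, "centromere": cen}
            for c, (l, cen) in self.chromosomes.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def default_genome(exclude_arms: Iterable[str] = ()) -> GenomeModel:
    """The default 22-autosome, 44-arm genome model."""
    return GenomeModel(
        {name: (length, cen) for name, length, cen in _DEFAULT_AUTOSOMES},
        exclude_arms=frozenset(exclude_arms),
    )


_SEGMENT_COLUMNS = ["chromosome", "start", "end", "copy_number"]


@dataclass
class SegmentProfile:
    """Per-sample segmented absolute copy number plus purity and ploidy.

    ``segments`` is a DataFrame with columns chromosome, start, end (1-based
    inclusive) and copy_number (absolute, >= 0).  Segments must not overlap
    within a chromosome.
    """

    sample: str
    segments: pd.DataFrame
    purity: float = float("nan")
    ploidy: float = float("nan")

    def __post_init__(self) -> None:
        seg = self.segments
        missing = [c for c in _SEGMENT_COLUMNS if c not in seg.columns]
        if missing:
            raise FormatError(f"sample {self.sample}: missing columns {missing}")
        seg = seg.copy()
        seg["chromosome"] = seg["chromosome"].astype(str)
        bad = seg["end"] < seg["start"]
        if bad.any():
            row = seg[bad].iloc[0]
            raise FormatError(
                f"sample {self.sample}: segment end < start at "
                f"{row.chromosome}:{row.start}-{row.end}"
            )
        if (seg["copy_number"] < 0).any():
            raise FormatError(f"sample {self.sample}: negative copy number")
        seg = seg.sort_values(["chromosome", "start"], kind="mergesort")
        for chrom, grp in seg.groupby("chromosome", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            overlap = starts[1:] <= ends[:-1]
            if overlap.any():
                i = int(np.flatnonzero(overlap)[0])
                raise FormatError(
                    f"sample {self.sample}: overlapping segments on "
                    f"chromosome {chrom} at {starts[i + 1]} <= {ends[i]}"
                )
        self.segments = seg.reset_index(drop=True)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves rounded up (2.5 -> 3)."""
    return int(math.floor(x + 0.5))


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Lower weighted median: the smallest value whose cumulative weight
    reaches half the total weight.

    Keeps the result within the set of observed values, so comparisons with
    an integer ploidy are well defined even when weights tie exactly.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("weighted_median: empty input")
    if v.shape != w.shape:
        raise ValueError("weighted_median: values and weights differ in length")
    if (w <= 0).any():
        raise ValueError("weighted_median: weights must be strictly positive")
    order = np.argsort(v, kind="mergesort")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    idx = int(np.searchsorted(cum, cum[-1] / 2.0, side="left"))
    return float(v[idx])


def split_at_centromere(
    profile: SegmentProfile, genome: GenomeModel
) -> SegmentProfile:
    """Split centromere-spanning segments and label every segment with its arm.

    Each half keeps the parent's copy number, and total covered length is
    conserved.  Sex-chromosome segments are dropped (with a log message);
    any other chromosome missing from the genome model is an error.
    """
    rows = []
    for r in profile.segments.itertuples():
        chrom = str(r.chromosome)
        if chrom in SEX_CHROMOSOMES:
            logger.debug(
                "sample %s: dropping sex-chromosome segment %s:%d-%d",
                profile.sample, chrom, r.start, r.end,
            )
            continue
        if chrom not in genome.chromosomes:
            raise FormatError(
                f"sample {profile.sample}: chromosome {chrom!r} not in genome model"
            )
        _, cen = genome.chromosomes[chrom]
        if r.start <= cen < r.end:
            rows.append((chrom, r.start, cen, r.copy_number, f"{chrom}p"))
            rows.append((chrom, cen + 1, r.end, r.copy_number, f"{chrom}q"))
        else:
            arm = f"{chrom}p" if r.end <= cen else f"{chrom}q"
            rows.append((chrom, r.start, r.end, r.copy_number, arm))
    seg = pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "copy_number", "arm"]
    )
    out = SegmentProfile(
        sample=profile.sample,
        segments=seg,
        purity=profile.purity,
        ploidy=profile.ploidy,
    )
    return out


def arm_copy_number(
    profile: SegmentProfile, genome: GenomeModel
) -> dict[str, float]:
    """Weighted-median copy number per arm (NaN where no segment overlaps).

    The profile need not be pre-split: overlap lengths are computed against
    the arm intervals directly, which is equivalent to splitting at the
    centromere first.
    """
    seg = split_at_centromere(profile, genome).segments
    out: dict[str, float] = {}
    by_arm = dict(tuple(seg.groupby("arm", sort=False))) if len(seg) else {}
    for arm in genome.arms:
        grp = by_arm.get(arm.name)
        if grp is None or len(grp) == 0:
            out[arm.name] = float("nan")
            continue
        starts = np.maximum(grp["start"].to_numpy(), arm.start)
        ends = np.minimum(grp["end"].to_numpy(), arm.end)
        lengths = (ends - starts + 1).astype(float)
        keep = lengths > 0
        if not keep.any():
            out[arm.name] = float("nan")
            continue
        out[arm.name] = weighted_median(
            grp["copy_number"].to_numpy()[keep], lengths[keep]
        )
    return out


def call_arm(arm_cn: float, ploidy: float) -> float:
    """+1 / 0 / -1 by comparing arm copy number with round(ploidy).

    A missing (NaN) arm copy number yields a missing call, not an error.
    """
    if ploidy <= 0 or not np.isfinite(ploidy):
        raise ValueError(f"ploidy must be positive and finite, got {ploidy}")
    if not np.isfinite(arm_cn):
        return float("nan")
    baseline = round_half_up(ploidy)
    if arm_cn > baseline:
        return 1.0
    if arm_cn < baseline:
        return -1.0
    return 0.0


def aneuploidy_score(calls: Mapping[str, float] | pd.Series) -> int:
    """Number of arms called amplified or deleted.

    Missing calls contribute nothing to the score (logged).
    """
    s = pd.Series(calls, dtype=float)
    n_missing = int(s.isna().sum())
    if n_missing:
        logger.info("aneuploidy_score: %d arm(s) missing, counted as neutral",
                    n_missing)
    return int((s.abs() == 1).sum())


@dataclass
class KaryotypeCall:
    """Per-arm copy numbers and calls for one sample, plus its AS."""

    sample: str
    arm_cn: dict[str, float]
    calls: dict[str, float]
    score: int


def karyotype(profile: SegmentProfile, genome: GenomeModel) -> KaryotypeCall:
    """Full arm-level workup of one sample: arm CNs, calls, AS."""
    cns = arm_copy_number(profile, genome)
    calls = {arm: call_arm(cn, profile.ploidy) for arm, cn in cns.items()}
    return KaryotypeCall(
        sample=profile.sample,
        arm_cn=cns,
        calls=calls,
        score=aneuploidy_score(calls),
    )


def segment_calls(profile: SegmentProfile, genome: GenomeModel) -> pd.DataFrame:
    """Per-segment amplification/deletion calls against rounded ploidy.

    By-product table mirroring the arm-level rule applied segment-wise.
    """
    seg = split_at_centromere(profile, genome).segments.copy()
    baseline = round_half_up(profile.ploidy)
    cn = seg["copy_number"].to_numpy(dtype=float)
    seg["call"] = np.sign(cn - baseline).astype(int)
    seg["sample"] = profile.sample
    return seg


def score_cohort(
    profiles: Iterable[SegmentProfile], genome: GenomeModel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Arm-call matrix (samples x arms) and per-sample AS table for a cohort."""
    call_rows, as_rows = {}, []
    for p in profiles:
        k = karyotype(p, genome)
        call_rows[p.sample] = k.calls
        as_rows.append(
            {"sample": p.sample, "AS": k.score,
             "ploidy": p.ploidy, "purity": p.purity}
        )
    calls = pd.DataFrame.from_dict(call_rows, orient="index")
    calls = calls.reindex(columns=genome.arm_names)
    calls.index.name = "sample"
    as_table = pd.DataFrame(as_rows).set_index("sample")
    return calls, as_table


def cohort_arm_summary(call_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-arm amplification/deletion/alteration frequencies across a cohort.

    Fractions are computed over samples with a non-missing call on the arm;
    an arm with no informative sample reports NaN fractions.
    """
    if call_matrix.shape[0] == 0:
        raise ValueError("cohort_arm_summary: need at least one sample")
    rows = []
    for arm in call_matrix.columns:
        col = call_matrix[arm].astype(float)
        informative = col.notna()
        n = int(informative.sum())
        if n == 0:
            rows.append({"arm": arm, "n": 0, "frac_amplified": float("nan"),
                         "frac_deleted": float("nan"),
                         "frac_altered": float("nan")})
            continue
        vals = col[informative]
        rows.append({
            "arm": arm,
            "n": n,
            "frac_amplified": float((vals == 1).mean()),
            "frac_deleted": float((vals == -1).mean()),
            "frac_altered": float((vals.abs() == 1).mean()),
        })
    return pd.DataFrame(rows).set_index("arm")
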