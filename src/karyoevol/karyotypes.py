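"""Karyotype formulae, arm-ratio morphology classes and derived traits.

A karyotype formula such as ``"12 m + 6sm + 4st"`` lists diploid counts of
chromosomes per morphology class — metacentric (m), submetacentric (sm),
subtelocentric (st) and telocentric (t); acrocentric (a) is treated as
telocentric. Six quantitative traits are derived per species: the haploid
chromosome number *n*, the haploid per-class counts (nm, nsm, nst, nt) and
the fundamental number *fn* (arm count, with m/sm/st two-armed and t
one-armed).

*fn* is stored on the **diploid** scale, matching the convention of the
assembled data table (e.g. *Amoimyrmex striatus*: nm = 10 haploid but
fn = 44 diploid arms); :attr:`TraitVector.fn_haploid` gives the haploid
value. A few published rows print an *fn* inconsistent with the two-armed
m/sm/st convention; the loader flags them rather than silently adopting
either value.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "CLASSES",
    "KaryotypeParseError",
    "KaryotypeRecord",
    "TraitVector",
    "parse_formula",
    "format_formula",
    "traits_from_counts",
    "classify_arm_ratio",
    "fundamental_number",
    "load_fixture",
    "trait_table",
    "TRAIT_NAMES",
]

CLASSES = ("m", "sm", "st", "t")
TRAIT_NAMES = ("n", "nm", "nsm", "nst", "nt", "fn")

# Levan arm-ratio (r = long/short) class boundaries
ARM_RATIO_BANDS = {"m": (1.0, 1.7), "sm": (1.7, 3.0), "st": (3.0, 7.0)}

_TERM_RE = re.compile(r"^\s*(\d+)\s*(m|sm|st|t|a)\s*$", re.IGNORECASE)


class KaryotypeParseError(ValueError):
    """A karyotype formula string could not be interpreted."""


def parse_formula(text: str) -> dict[str, int]:
    """Parse a formula like ``"2 m + 6sm + 16st + 14 t"`` into diploid
    per-class counts. Absent classes get count 0; ``a`` (acrocentric)
    is folded into ``t``."""
    if text is None or not text.strip():
        raise KaryotypeParseError("empty karyotype formula")
    counts = dict.fromkeys(CLASSES, 0)
    for term in text.split("+"):
        match = _TERM_RE.match(term)
        if match is None:
            raise KaryotypeParseError(
                f"cannot parse term {term.strip()!r} in formula {text!r}")
        count, cls = int(match.group(1)), match.group(2).lower()
        if cls == "a":
            cls = "t"
        counts[cls] += count
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Inverse of :func:`parse_formula` (omits zero-count classes)."""
    parts = [f"{counts[c]}{c}" for c in CLASSES if counts.get(c, 0) > 0]
    if not parts:
        raise KaryotypeParseError("all class counts are zero")
    return " + ".join(parts)


def fundamental_number(counts: dict[str, int]) -> int:
    """Arm count on the scale of ``counts``: m/sm/st contribute two arms
    each, t one."""
    return 2 * (counts["m"] + counts["sm"] + counts["st"]) + counts["t"]


@dataclass(frozen=True)
class TraitVector:
    """The six karyotype traits of one species.

    ``n`` and the per-class counts are haploid; ``fn`` is the diploid arm
    count (the scale the assembled table prints).
    """

    n: int
    nm: int
    nsm: int
    nst: int
    nt: int
    fn: int

    @property
    def fn_haploid(self) -> int:
        return self.fn // 2

    def as_dict(self) -> dict[str, int]:
        return {k: getattr(self, k) for k in TRAIT_NAMES}


def traits_from_counts(counts: dict[str, int], strict: bool = True) -> TraitVector:
    """Derive the trait vector from diploid per-class counts.

    Halving diploid counts must be exact; with ``strict=False`` an odd
    class count is rounded down on the haploid scale (heterozygous
    rearrangements) while *n* still uses the exact total.
    """
    total = sum(counts.get(c, 0) for c in CLASSES)
    if total <= 0:
        raise ValueError("karyotype has zero chromosomes")
    if total % 2:
        raise ValueError(f"diploid total {total} is odd")
    if strict:
        odd = [c for c in CLASSES if counts.get(c, 0) % 2]
        if odd:
            raise ValueError(f"odd diploid count for class(es) {odd}; "
                             "use strict=False to floor-halve")
    return TraitVector(
        n=total // 2,
        nm=counts.get("m", 0) // 2,
        nsm=counts.get("sm", 0) // 2,
        nst=counts.get("st", 0) // 2,
        nt=counts.get("t", 0) // 2,
        fn=fundamental_number({c: counts.get(c, 0) for c in CLASSES}),
    )


def classify_arm_ratio(long_arm: float, short_arm: float) -> str:
    """Morphology class from the arm ratio r = long/short (Levan bands:
    m [1, 1.7), sm [1.7, 3), st [3, 7), t [7, inf); a missing short arm
    is telocentric)."""
    if long_arm < short_arm:
        raise ValueError("long arm shorter than short arm")
    if long_arm <= 0:
        raise ValueError("chromosome with no arms")
    if short_arm == 0:
        return "t"
    r = long_arm / short_arm
    for cls, (lo, hi) in ARM_RATIO_BANDS.items():
        if lo <= r < hi:
            return cls
    return "t"


@dataclass(frozen=True)
class KaryotypeRecord:
    """One published karyotype: a row of the assembled cytogenetic table."""

    taxon: str
    haploid_n: int
    diploid_2n: int
    formula: dict[str, int]
    locality: str = ""
    preferred: bool = True
    group: str = "leafcutting"
    genome_mbp: float | None = None
    fn_printed: int | None = None

    def __post_init__(self):
        total = sum(self.formula.get(c, 0) for c in CLASSES)
        if total != self.diploid_2n:
            raise ValueError(
                f"{self.taxon}: formula sums to {total}, not 2n={self.diploid_2n}")
        if self.diploid_2n != 2 * self.haploid_n:
            raise ValueError(f"{self.taxon}: 2n != 2×n")

    @property
    def traits(self) -> TraitVector:
        return traits_from_counts(self.formula)

    @property
    def fn_consistent(self) -> bool:
        """Whether the published fn matches the two-armed-st convention."""
        if self.fn_printed is None:
            return True
        return self.fn_printed == fundamental_number(self.formula)


def _fixture_frame() -> pd.DataFrame:
    with resources.files("karyoevol.data").joinpath(
            "leafcutter_karyotypes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_fixture(include_outgroups: bool = True) -> list[KaryotypeRecord]:
    """All records of the packaged cytogenetic table, in table order.

    Species with more than one published karyotype carry one record with
    ``preferred=True`` (the baseline measurement-based row, the first
    listed per species) used by default in downstream analyses.
    """
    df = _fixture_frame()
    if not include_outgroups:
        df = df[df["group"] == "leafcutting"]
    records = []
    for row in df.itertuples(index=False):
        records.append(KaryotypeRecord(
            taxon=row.taxon,
            haploid_n=int(row.haploid_n),
            diploid_2n=int(row.diploid_2n),
            formula=parse_formula(row.formula),
            locality="" if pd.isna(row.locality) else str(row.locality),
            preferred=bool(row.preferred),
            group=row.group,
            genome_mbp=None if pd.isna(row.genome_mbp) else float(row.genome_mbp),
            fn_printed=None if pd.isna(row.fn_printed) else int(row.fn_printed),
        ))
    return records


def trait_table(records: list[KaryotypeRecord] | None = None,
                preferred_only: bool = True,
                log_transform: bool = False) -> pd.DataFrame:
    """Per-species trait table (taxon, n, nm, nsm, nst, nt, fn).

    With ``preferred_only`` exactly one row per species is returned. The
    optional transform is log(x + 1), tolerating the zero counts that
    occur in several classes (e.g. nt = 0 throughout *Atta*).
    """
    if records is None:
        records = load_fixture()
    if preferred_only:
        seen: dict[str, KaryotypeRecord] = {}
        for rec in records:
            if rec.preferred and rec.taxon not in seen:
                seen[rec.taxon] = rec
        records = list(seen.values())
    rows = []
    for rec in records:
        tv = rec.traits.as_dict()
        if log_transform:
            tv = {k: math.log(v + 1.0) for k, v in tv.items()}
        rows.append({"taxon": rec.taxon, **tv})
    df = pd.DataFrame(rows)
    if preferred_only and df["taxon"].duplicated().any():  # pragma: no cover
        raise AssertionError("duplicate preferred record per species")
    return df
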