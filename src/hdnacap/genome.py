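"""Chromosomes, centromeres, SSR marker panels and genomic feature tracks.

Coordinates are 1-based bp in files and converted to 0-based half-open
intervals internally; bedGraph input is already 0-based half-open.
Allele labels are capillary-electrophoresis fragment sizes (integers); the
abstract roles a/b (maternal) and c/d (paternal) are assigned per locus with
``a`` the smaller maternal fragment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TRACK_KINDS = (
    "recomb_rate",
    "methylation",
    "ltr_gypsy",
    "low_complexity",
    "gene_density",
)

#: track kinds whose values are proportions and must be non-negative
_NONNEG_KINDS = frozenset({"ltr_gypsy", "low_complexity", "gene_density"})


class ValidationError(ValueError):
    """Raised when an input file or domain object violates an invariant."""


@dataclass(frozen=True)
class ChromosomeModel:
    """A chromosome with a single centromere interval (0-based, half-open)."""

    name: str
    length_bp: int
    centromere_start_bp: int
    centromere_end_bp: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValidationError(f"{self.name}: length_bp must be positive")
        if not (0 <= self.centromere_start_bp < self.centromere_end_bp <= self.length_bp):
            raise ValidationError(
                f"{self.name}: centromere interval "
                f"[{self.centromere_start_bp}, {self.centromere_end_bp}) "
                f"must satisfy 0 <= start < end <= length ({self.length_bp})"
            )

    def contains_centromere(self, pos_bp: int) -> bool:
        return self.centromere_start_bp <= pos_bp < self.centromere_end_bp


@dataclass(frozen=True)
class MarkerLocus:
    """An SSR site with a maternal allele pair and one or two paternal alleles.

    Eligibility for hDNA detection (maternal heterozygosity, no allele shared
    with the paternal parent) is *screened*, not enforced at construction, so
    that raw panels can be loaded and triaged.
    """

    marker_id: str
    chrom: str
    pos_bp: int
    maternal_alleles: tuple[int, int]
    paternal_alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.pos_bp < 0:
            raise ValidationError(f"{self.marker_id}: pos_bp must be >= 0")
        if len(self.maternal_alleles) != 2:
            raise ValidationError(f"{self.marker_id}: exactly two maternal alleles required")
        if not 1 <= len(self.paternal_alleles) <= 2:
            raise ValidationError(f"{self.marker_id}: one or two paternal alleles required")
        # canonical order: a = smaller maternal fragment, c = smaller paternal
        object.__setattr__(self, "maternal_alleles", tuple(sorted(self.maternal_alleles)))
        object.__setattr__(
            self, "paternal_alleles", tuple(sorted(set(self.paternal_alleles)))
        )

    @property
    def allele_a(self) -> int:
        return self.maternal_alleles[0]

    @property
    def allele_b(self) -> int:
        return self.maternal_alleles[1]

    def eligibility_failures(self) -> list[str]:
        """Reasons this locus cannot be used for hDNA detection (empty if eligible)."""
        reasons = []
        if self.maternal_alleles[0] == self.maternal_alleles[1]:
            reasons.append("maternal homozygous")
        if set(self.maternal_alleles) & set(self.paternal_alleles):
            reasons.append("shared allele")
        return reasons

    @property
    def is_eligible(self) -> bool:
        return not self.eligibility_failures()


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered collection of marker loci, sorted by (chrom, pos_bp)."""

    loci: tuple[MarkerLocus, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.loci, key=lambda m: (m.chrom, m.pos_bp)))
        object.__setattr__(self, "loci", ordered)
        ids = [m.marker_id for m in ordered]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate marker ids: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, marker_id: str) -> MarkerLocus:
        for m in self.loci:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.loci]

    def on_chromosome(self, chrom: str) -> "MarkerPanel":
        return MarkerPanel(tuple(m for m in self.loci if m.chrom == chrom))

    def subset(self, marker_ids: Iterable[str]) -> "MarkerPanel":
        wanted = set(marker_ids)
        missing = wanted - set(self.marker_ids)
        if missing:
            raise KeyError(f"markers not in panel: {sorted(missing)}")
        return MarkerPanel(tuple(m for m in self.loci if m.marker_id in wanted))

    def positions(self, chrom: str | None = None) -> np.ndarray:
        loci = self.loci if chrom is None else tuple(m for m in self.loci if m.chrom == chrom)
        return np.array([m.pos_bp for m in loci], dtype=np.int64)


@dataclass(frozen=True)
class FeatureTrack:
    """Binned genomic feature values (0-based, half-open, sorted, non-overlapping)."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        values = np.asarray(self.values, dtype=float)
        if self.kind not in TRACK_KINDS:
            raise ValidationError(f"unknown track kind {self.kind!r}")
        if not (len(starts) == len(ends) == len(values)):
            raise ValidationError("starts/ends/values length mismatch")
        if np.any(ends <= starts):
            raise ValidationError(f"{self.kind}: empty or inverted bin")
        if np.any(np.diff(starts) < 0) or np.any(starts[1:] < ends[:-1]):
            raise ValidationError(f"{self.kind}: bins must be sorted and non-overlapping")
        if not np.all(np.isfinite(values)):
            raise ValidationError(f"{self.kind}: non-finite value")
        if self.kind in _NONNEG_KINDS and np.any(values < 0):
            raise ValidationError(f"{self.kind}: values must be >= 0")
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.starts)

    def value_at(self, pos_bp: int | np.ndarray) -> np.ndarray:
        """Value of the bin containing each position; NaN outside coverage."""
        pos = np.atleast_1d(np.asarray(pos_bp, dtype=np.int64))
        idx = np.searchsorted(self.starts, pos, side="right") - 1
        out = np.full(pos.shape, np.nan)
        ok = (idx >= 0) & (pos < self.ends[np.clip(idx, 0, len(self) - 1)])
        out[ok] = self.values[idx[ok]]
        return out

    def covers(self, pos_bp: int) -> bool:
        return bool(np.isfinite(self.value_at(pos_bp))[0])


def screen_markers(panel: MarkerPanel) -> tuple[MarkerPanel, list[tuple[str, str]]]:
    """Split a panel into hDNA-eligible loci and rejected (marker_id, reason) pairs.

    A locus is eligible when the female parent is heterozygous, no maternal
    allele is shared with the male parent, and the position is known (enforced
    at construction). Screening an already-eligible panel rejects nothing.
    """
    eligible, rejected = [], []
    for m in panel:
        failures = m.eligibility_failures()
        if failures:
            rejected.append((m.marker_id, "; ".join(failures)))
        else:
            eligible.append(m)
    return MarkerPanel(tuple(eligible)), rejected


def locus_centromere_distance(locus: MarkerLocus, chrom: ChromosomeModel) -> float:
    """Distance (Mbp) from a locus to the nearest centromere boundary; 0 inside."""
    if locus.chrom != chrom.name:
        raise ValidationError(
            f"locus {locus.marker_id} is on {locus.chrom}, not {chrom.name}"
        )
    return position_centromere_distance(locus.pos_bp, chrom)


def position_centromere_distance(pos_bp: float, chrom: ChromosomeModel) -> float:
    if pos_bp < chrom.centromere_start_bp:
        return (chrom.centromere_start_bp - pos_bp) / 1e6
    if pos_bp >= chrom.centromere_end_bp:
        return (pos_bp - chrom.centromere_end_bp) / 1e6
    return 0.0


# ---------------------------------------------------------------------------
# I/O

_PANEL_COLUMNS = ["marker_id", "chrom", "pos_bp", "maternal_a", "maternal_b", "paternal"]


def _parse_sizes(text: str) -> tuple[int, ...]:
    return tuple(int(round(float(tok))) for tok in str(text).split(",") if tok.strip())


def load_marker_panel(path: str | Path, require_eligible: bool = True) -> MarkerPanel:
    """Read a marker panel from TSV.

    Columns: marker_id, chrom, pos_bp (1-based in the file), maternal_a,
    maternal_b, paternal (comma-separated fragment sizes). With
    ``require_eligible`` (default) a locus failing the screening conditions is
    a :class:`ValidationError`; pass ``require_eligible=False`` to load a raw
    panel for :func:`screen_markers` triage.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty marker file, returning empty panel")
        return MarkerPanel(())
    missing_cols = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {missing_cols}")
    if df.empty:
        warnings.warn(f"{path}: empty marker file, returning empty panel")
        return MarkerPanel(())
    loci = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            locus = MarkerLocus(
                marker_id=str(row["marker_id"]),
                chrom=str(row["chrom"]),
                pos_bp=int(row["pos_bp"]) - 1,  # 1-based file -> 0-based internal
                maternal_alleles=(int(row["maternal_a"]), int(row["maternal_b"])),
                paternal_alleles=_parse_sizes(row["paternal"]),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} line {line_no}: {exc}") from exc
        if require_eligible:
            failures = locus.eligibility_failures()
            if failures:
                raise ValidationError(
                    f"{path} line {line_no}: marker {locus.marker_id} ineligible "
                    f"({'; '.join(failures)})"
                )
        loci.append(locus)
    return MarkerPanel(tuple(loci))


def write_marker_panel(panel: MarkerPanel, path: str | Path) -> None:
    rows = [
        {
            "marker_id": m.marker_id,
            "chrom": m.chrom,
            "pos_bp": m.pos_bp + 1,  # back to 1-based
            "maternal_a": m.maternal_alleles[0],
            "maternal_b": m.maternal_alleles[1],
            "paternal": ",".join(str(a) for a in m.paternal_alleles),
        }
        for m in panel
    ]
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_feature_track(path: str | Path, kind: str) -> FeatureTrack:
    """Read a standard 4-column bedGraph (chrom, start, end, value) as one track.

    All rows must belong to a single chromosome; bins must be sorted and
    non-overlapping.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#", dtype={"chrom": str},
    )
    if df.empty:
        raise ValidationError(f"{path}: empty bedGraph")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValidationError(f"{path}: expected one chromosome, found {list(chroms)}")
    return FeatureTrack(
        chrom=str(chroms[0]),
        starts=df["start"].to_numpy(np.int64),
        ends=df["end"].to_numpy(np.int64),
        values=df["value"].to_numpy(float),
        kind=kind,
    )


def write_feature_track(track: FeatureTrack, path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": track.chrom,
            "start": track.starts,
            "end": track.ends,
            "value": track.values,
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def load_chromosomes(path: str | Path) -> dict[str, ChromosomeModel]:
    """Read chromosome/centromere definitions from YAML.

    Layout::

        Chr19:
          length_bp: 15900000
          centromere: [5300000, 6700000]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: expected a mapping of chromosome names")
    out = {}
    for name, spec in raw.items():
        try:
            cen = spec["centromere"]
            out[name] = ChromosomeModel(
                name=str(name),
                length_bp=int(spec["length_bp"]),
                centromere_start_bp=int(cen[0]),
                centromere_end_bp=int(cen[1]),
            )
        except (KeyError, TypeError, IndexError) as exc:
            raise ValidationError(f"{path}: malformed entry for {name}: {exc}") from exc
    return out


def write_chromosomes(chroms: dict[str, ChromosomeModel] | Sequence[ChromosomeModel],
                      path: str | Path) -> None:
    if not isinstance(chroms, dict):
        chroms = {c.name: c for c in chroms}
    payload = {
        name: {
            "length_bp": c.length_bp,
            "centromere": [c.centromere_start_bp, c.centromere_end_bp],
        }
        for name, c in chroms.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
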