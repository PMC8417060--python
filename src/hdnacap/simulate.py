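"""Forward simulation of female meiosis with hDNA capture in 2n eggs.

The generative model abstracts the assay rather than full bivalent
bookkeeping: each meiosis deposits a Poisson number of recombination events
along the chromosome, positioned by a recombination landscape; each event
leaves a heteroduplex (hDNA) tract of geometric length on the chromatid pair
that ends up in the functional megaspore. A tract escapes mismatch repair
with probability ``1 - p_mmr``; inhibition of the first post-meiotic mitosis
(embryo-sac chromosome doubling) then captures both strands in one unreduced
2n egg, so an SSR locus inside an unrepaired tract is maternally
heterozygous (``ab``) in the resulting allotriploid. Repaired tracts resolve
to a single allele (conversion to the invading allele with probability
``p_conversion``). Loci outside tracts carry the background megaspore
haplotype, an aa/bb mosaic over the segments between event boundaries.

Fertilisation adds one paternal allele per locus, giving the triploid
genotype table that the calling module consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import ChromosomeModel, FeatureTrack, MarkerPanel, ValidationError

MISSING_TOKEN = "."


@dataclass(frozen=True)
class LandscapeWeights:
    """Log-linear weights applied to z-scored feature tracks.

    The sign conventions mirror the biology being emulated: recombination is
    suppressed near the centromere and in methylated / LTR-Gypsy-rich
    regions, and elevated in AT-low-complexity and gene-dense regions.
    ``w_centromere`` is an additive log-intensity offset inside the
    centromere interval; ``-inf`` masks it completely.
    """

    w_centromere: float = -2.0
    w_methylation: float = -0.6
    w_ltr: float = -0.6
    w_lowcomp: float = 0.4
    w_gene_density: float = 0.4
    w_recomb_rate: float = 0.0

    KIND_ATTRS = {
        "methylation": "w_methylation",
        "ltr_gypsy": "w_ltr",
        "low_complexity": "w_lowcomp",
        "gene_density": "w_gene_density",
        "recomb_rate": "w_recomb_rate",
    }

    def weight_for(self, kind: str) -> float:
        return getattr(self, self.KIND_ATTRS[kind])


@dataclass(frozen=True)
class RecombinationLandscape:
    """Piecewise-constant relative event density over a chromosome.

    ``density`` is per-bp probability mass: sum(density * segment length) = 1.
    """

    chrom: str
    edges: np.ndarray      # segment boundaries, length n+1, edges[0]=0
    density: np.ndarray    # per-bp density, length n

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.int64)
        density = np.asarray(self.density, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValidationError("landscape edges must be strictly increasing")
        if np.any(density < 0):
            raise ValidationError("landscape density must be non-negative")
        mass = float(np.sum(density * np.diff(edges)))
        if not math.isclose(mass, 1.0, rel_tol=1e-9):
            raise ValidationError(f"landscape density integrates to {mass}, not 1")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "density", density)
        object.__setattr__(self, "_cum", np.concatenate(
            [[0.0], np.cumsum(density * np.diff(edges))]))

    @property
    def length_bp(self) -> int:
        return int(self.edges[-1])

    def intensity_at(self, pos_bp: int | np.ndarray) -> np.ndarray:
        pos = np.atleast_1d(np.asarray(pos_bp, dtype=np.int64))
        idx = np.clip(np.searchsorted(self.edges, pos, side="right") - 1,
                      0, len(self.density) - 1)
        return self.density[idx]

    def sample_positions(self, k: int, rng: np.random.Generator) -> np.ndarray:
        """Draw k event start positions (bp) from the landscape density."""
        if k == 0:
            return np.empty(0, dtype=np.int64)
        u = rng.random(k) * self._cum[-1]
        seg = np.clip(np.searchsorted(self._cum, u, side="right") - 1,
                      0, len(self.density) - 1)
        # uniform within the chosen segment
        frac = rng.random(k)
        lo, hi = self.edges[seg], self.edges[seg + 1]
        return (lo + frac * (hi - lo)).astype(np.int64)


def build_landscape(
    tracks: Sequence[FeatureTrack],
    chrom: ChromosomeModel,
    weights: LandscapeWeights | None = None,
    fill_value: float | None = None,
) -> RecombinationLandscape:
    """Combine feature tracks into a normalized per-bp event density.

    Log-intensity at position x is the weighted sum of length-standardized
    track values, plus ``w_centromere`` inside the centromere interval. With
    all weights zero the density is uniform. Positions not covered by a track
    raise unless ``fill_value`` supplies the raw track value to assume there.
    """
    weights = weights or LandscapeWeights()
    cuts = {0, chrom.length_bp, chrom.centromere_start_bp, chrom.centromere_end_bp}
    for t in tracks:
        if t.chrom != chrom.name:
            raise ValidationError(f"track {t.kind} is on {t.chrom}, not {chrom.name}")
        cuts.update(int(s) for s in np.clip(t.starts, 0, chrom.length_bp))
        cuts.update(int(e) for e in np.clip(t.ends, 0, chrom.length_bp))
    edges = np.array(sorted(cuts), dtype=np.int64)
    mids = (edges[:-1] + edges[1:]) // 2
    seg_len = np.diff(edges).astype(float)

    log_int = np.zeros(len(mids))
    for t in tracks:
        w = weights.weight_for(t.kind)
        vals = t.value_at(mids)
        uncovered = ~np.isfinite(vals)
        if np.any(uncovered):
            if fill_value is None:
                bad = edges[:-1][uncovered]
                raise ValidationError(
                    f"track {t.kind} does not cover segments starting at "
                    f"{bad[:5].tolist()}... (set fill_value to allow)"
                )
            vals = np.where(uncovered, fill_value, vals)
        if w == 0.0:
            continue
        mean = np.average(vals, weights=seg_len)
        sd = math.sqrt(max(np.average((vals - mean) ** 2, weights=seg_len), 0.0))
        z = (vals - mean) / sd if sd > 0 else np.zeros_like(vals)
        log_int += w * z

    intensity = np.exp(log_int)
    in_cen = (edges[:-1] >= chrom.centromere_start_bp) & (edges[1:] <= chrom.centromere_end_bp)
    if weights.w_centromere == -np.inf:
        intensity[in_cen] = 0.0
    else:
        intensity[in_cen] *= math.exp(weights.w_centromere)
    mass = float(np.sum(intensity * seg_len))
    if mass <= 0:
        raise ValidationError("landscape has zero total intensity")
    return RecombinationLandscape(chrom=chrom.name, edges=edges, density=intensity / mass)


@dataclass(frozen=True)
class MeiosisParams:
    """Parameters of the per-meiosis hDNA tract process.

    Defaults are illustrative: they place per-locus hDNA frequencies in the
    ~0.1-0.9 range observed with dense SSR panels on a mid-size Populus
    chromosome. They are not inferred from any dataset.
    """

    lambda_events: float = 14.0       # Poisson mean RE count per meiosis
    tract_mean_bp: float = 1.8e6      # geometric mean hDNA tract length
    p_mmr: float = 0.15               # P(tract mismatch repaired before capture)
    p_conversion: float = 0.5         # given repair, P(convert to invading allele)

    def __post_init__(self) -> None:
        if self.lambda_events < 0:
            raise ValidationError("lambda_events must be >= 0")
        if self.tract_mean_bp < 1:
            raise ValidationError("tract_mean_bp must be >= 1")
        for name in ("p_mmr", "p_conversion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class Tract:
    start_bp: int
    end_bp: int          # half-open
    repaired: bool

    def covers(self, pos_bp: int) -> bool:
        return self.start_bp <= pos_bp < self.end_bp


@dataclass
class CapturedEgg:
    """Ground truth for one captured 2n egg: per-locus maternal genotype + tracts."""

    genotypes: dict[str, str]        # marker_id -> 'aa' | 'bb' | 'ab'
    tracts: list[Tract]
    n_events: int


def simulate_meiosis(
    params: MeiosisParams,
    landscape: RecombinationLandscape,
    panel: MarkerPanel,
    chrom: ChromosomeModel,
    rng: np.random.Generator,
) -> CapturedEgg:
    """Simulate one female meiosis and the captured 2n egg's maternal genotypes.

    A locus genotype is ``ab`` iff an unrepaired tract overlaps it; repaired
    tracts resolve to one allele across the whole tract; everything else
    carries the background aa/bb mosaic (one coin flip per segment between
    event boundaries).
    """
    loci = panel.on_chromosome(chrom.name)
    if len(loci) == 0:
        raise ValidationError(f"no markers on {chrom.name}")

    k = int(rng.poisson(params.lambda_events))
    starts = landscape.sample_positions(k, rng)
    lengths = rng.geometric(1.0 / params.tract_mean_bp, size=k) if k else np.empty(0, np.int64)
    ends = np.minimum(starts + lengths, chrom.length_bp)
    repaired = rng.random(k) < params.p_mmr
    converted = rng.random(k) < params.p_conversion
    tracts = [Tract(int(s), int(e), bool(r)) for s, e, r in zip(starts, ends, repaired)]

    # background haplotype mosaic over segments between tract boundaries
    bounds = np.unique(np.concatenate([[0, chrom.length_bp], starts, ends]))
    seg_is_a = rng.random(len(bounds) - 1) < 0.5  # background allele per segment

    pos = loci.positions(chrom.name)
    seg_idx = np.clip(np.searchsorted(bounds, pos, side="right") - 1, 0, len(seg_is_a) - 1)
    background = np.where(seg_is_a[seg_idx], "aa", "bb")

    genotypes = {}
    for j, m in enumerate(loci):
        p = pos[j]
        covering = [i for i in range(k) if starts[i] <= p < ends[i]]
        unrep = [i for i in covering if not repaired[i]]
        if unrep:
            g = "ab"
        elif covering:
            i = covering[0]  # deterministic tie-break: earliest-sampled tract
            base = "aa" if seg_is_a[min(np.searchsorted(bounds, starts[i], side="right") - 1,
                                        len(seg_is_a) - 1)] else "bb"
            if converted[i]:
                g = "bb" if base == "aa" else "aa"
            else:
                g = base
        else:
            g = str(background[j])
        genotypes[m.marker_id] = g
    return CapturedEgg(genotypes=genotypes, tracts=tracts, n_events=k)


class TriploidGenotypeTable:
    """Individuals x loci table of observed allele multisets (fragment sizes).

    Each non-missing cell holds one paternal allele plus one or two maternal
    alleles, as a sorted tuple of ints. Missing cells are ``None``.
    """

    def __init__(self, data: pd.DataFrame):
        self.data = data  # index: individual ids, columns: marker ids, object cells

    @property
    def individuals(self) -> list[str]:
        return list(self.data.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.data.columns)

    def cell(self, individual: str, marker_id: str) -> tuple[int, ...] | None:
        return self.data.at[individual, marker_id]

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        return isinstance(other, TriploidGenotypeTable) and self.data.equals(other.data)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.map(
            lambda c: MISSING_TOKEN if c is None else ",".join(str(a) for a in c)
        )
        out.index.name = "individual"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TriploidGenotypeTable":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)

        def parse(cell):
            if pd.isna(cell) or cell.strip() in (MISSING_TOKEN, ""):
                return None
            return tuple(sorted(int(round(float(t))) for t in cell.split(",")))

        return cls(df.map(parse))


def generate_population(
    params: MeiosisParams,
    landscape: RecombinationLandscape,
    panel: MarkerPanel,
    chrom: ChromosomeModel,
    n_individuals: int,
    missing_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
    id_prefix: str = "T",
) -> tuple[TriploidGenotypeTable, list[CapturedEgg]]:
    """Simulate a triploid population: one captured egg + one paternal gamete each.

    Returns the observed genotype table (with independent missingness at
    ``missing_rate``) and the per-individual ground truth.
    """
    if n_individuals < 1:
        raise ValidationError("n_individuals must be >= 1")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValidationError("missing_rate must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    loci = panel.on_chromosome(chrom.name)

    rows, truth = [], []
    ids = [f"{id_prefix}{i + 1:04d}" for i in range(n_individuals)]
    for _ in ids:
        egg = simulate_meiosis(params, landscape, loci, chrom, rng)
        truth.append(egg)
        row = {}
        for m in loci:
            g = egg.genotypes[m.marker_id]
            pat = m.paternal_alleles[int(rng.integers(len(m.paternal_alleles)))]
            if g == "ab":
                alleles = (m.allele_a, m.allele_b, pat)
            elif g == "aa":
                alleles = (m.allele_a, pat)
            else:
                alleles = (m.allele_b, pat)
            if missing_rate > 0 and rng.random() < missing_rate:
                row[m.marker_id] = None
            else:
                row[m.marker_id] = tuple(sorted(alleles))
        rows.append(row)
    data = pd.DataFrame(rows, index=pd.Index(ids, name="individual"),
                        columns=loci.marker_ids, dtype=object)
    data = data.where(data.notna(), None)
    return TriploidGenotypeTable(data), truth


def truth_hdna_indicator(truth: Sequence[CapturedEgg], marker_id: str) -> np.ndarray:
    """Boolean per-individual indicator: locus genotype ab in the captured egg."""
    return np.array([egg.genotypes[marker_id] == "ab" for egg in truth])


# ---------------------------------------------------------------------------
# Analytic coverage probability (independent of the simulator's sampling path)

def tract_coverage_probability(
    pos_bp: int,
    params: MeiosisParams,
    landscape: RecombinationLandscape,
) -> float:
    """P(a locus is maternally heterozygous) under the tract process, in closed form.

    A single event started at s with geometric length L (support >= 1,
    success 1/mean) covers x iff s <= x and L > x - s. Summing the geometric
    tail over each constant-density landscape segment gives the single-tract
    coverage probability q1(x); the number of *unrepaired* covering tracts is
    Poisson with mean lambda * (1 - p_mmr) * q1(x), so
    P(ab) = 1 - exp(-lambda * (1 - p_mmr) * q1(x)).
    """
    p = 1.0 / params.tract_mean_bp
    log_r = math.log1p(-p)  # r = 1 - p, P(L > j) = r^j
    q1 = 0.0
    for lo, hi, dens in zip(landscape.edges[:-1], landscape.edges[1:], landscape.density):
        if dens == 0.0 or lo > pos_bp:
            continue
        hi = min(int(hi), pos_bp + 1)  # starts s in [lo, hi), s <= x
        n = hi - lo
        if n <= 0:
            continue
        # sum_{s=lo}^{hi-1} r^(x-s) = r^(x-hi+1) * (1 - r^n) / (1 - r)
        j_min = pos_bp - hi + 1
        q1 += dens * math.exp(j_min * log_r) * (-math.expm1(n * log_r)) / p
    mu = params.lambda_events * (1.0 - params.p_mmr) * q1
    return -math.expm1(-mu)
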