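"""Correlates of per-locus hDNA frequency: centromere distance and feature tracks.

hDNA frequency is regressed (in percent, to keep intercepts on the scale a
breeder reads off a frequency table) on locus-centromere distance (Mbp) and
on per-locus genomic feature values (the containing track bin's value, no
interpolation). Plain R^2 = r^2 is reported, never adjusted R^2, so it is
always in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import (
    ChromosomeModel,
    FeatureTrack,
    MarkerPanel,
    ValidationError,
    position_centromere_distance,
)
from .linfit import LinearFitResult, linear_fit


def correlate_hf_distance(
    hf: pd.DataFrame,
    panel: MarkerPanel,
    chrom: ChromosomeModel,
) -> LinearFitResult:
    """OLS of hDNA frequency (%) on locus-centromere distance (Mbp)."""
    sub = hf[hf["chrom"] == chrom.name].dropna(subset=["HF"])
    if len(sub) < 3:
        raise ValidationError(f"need >= 3 loci with defined HF on {chrom.name}")
    dist = np.array(
        [position_centromere_distance(p, chrom) for p in sub["pos_bp"]], dtype=float
    )
    return linear_fit(dist, 100.0 * sub["HF"].to_numpy())


def fit_hf_vs_track(
    hf: pd.DataFrame,
    track: FeatureTrack,
    panel: MarkerPanel,
) -> LinearFitResult:
    """OLS of hDNA frequency (%) on the feature value at each locus.

    The predictor at a locus is the value of the track bin containing its
    position; a locus outside track coverage is an error naming the loci. A
    constant predictor yields a degenerate-flagged result.
    """
    sub = hf[hf["chrom"] == track.chrom].dropna(subset=["HF"])
    if len(sub) < 3:
        raise ValidationError(f"need >= 3 loci with defined HF on {track.chrom}")
    vals = track.value_at(sub["pos_bp"].to_numpy())
    uncovered = ~np.isfinite(vals)
    if np.any(uncovered):
        bad = sub["marker_id"].to_numpy()[uncovered]
        raise ValidationError(
            f"loci outside {track.kind} track coverage: {', '.join(bad[:10])}"
        )
    return linear_fit(vals, 100.0 * sub["HF"].to_numpy())


def correlation_table(
    hf: pd.DataFrame,
    tracks: dict[str, FeatureTrack],
    panel: MarkerPanel,
    chrom: ChromosomeModel,
    genotype: str = "",
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Per-predictor linear-fit table (distance + each feature track).

    Per-fit p-values are reported without family-wise correction by default;
    ``bh_adjust=True`` appends Benjamini-Hochberg adjusted q-values.
    """
    rows = []

    def add(kind: str, res: LinearFitResult):
        rows.append(
            {
                "genotype": genotype,
                "chrom": chrom.name,
                "predictor_kind": kind,
                "slope": res.slope,
                "intercept": res.intercept,
                "R2": res.r_squared,
                "p": res.p_value,
                "n": res.n,
            }
        )

    add("centromere_distance", correlate_hf_distance(hf, panel, chrom))
    for kind in sorted(tracks):
        add(kind, fit_hf_vs_track(hf, tracks[kind], panel))
    out = pd.DataFrame(rows)
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        finite = out["p"].notna()
        q = np.full(len(out), np.nan)
        if finite.any():
            q[finite.to_numpy()] = multipletests(
                out.loc[finite, "p"].to_numpy(), method="fdr_bh"
            )[1]
        out["q_bh"] = q
    return out


@dataclass(frozen=True)
class BinnedDensity:
    """Uniformly re-binned gene mass along one chromosome (heat-map row)."""

    chrom: str
    bin_size_bp: int
    values: np.ndarray  # per-bin mass, tiles [0, length_bp)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if self.bin_size_bp <= 0:
            raise ValidationError("bin_size_bp must be positive")
        if np.any(values < 0):
            raise ValidationError("binned density must be >= 0")
        object.__setattr__(self, "values", values)

    @property
    def starts(self) -> np.ndarray:
        return np.arange(len(self.values), dtype=np.int64) * self.bin_size_bp

    def total_mass(self) -> float:
        return float(self.values.sum())


def bin_gene_density(
    track: FeatureTrack,
    chrom: ChromosomeModel,
    bin_size_bp: int,
) -> BinnedDensity:
    """Re-bin a gene-density track onto uniform bins, conserving total mass.

    Each input bin's value is treated as a mass (gene count) and distributed
    over output bins in proportion to overlap length, so the summed output
    equals the summed input exactly. A bin size larger than the chromosome
    yields a single bin (with a warning).
    """
    if track.kind != "gene_density":
        raise ValidationError(f"expected a gene_density track, got {track.kind}")
    if bin_size_bp <= 0:
        raise ValidationError("bin_size_bp must be positive")
    if bin_size_bp > chrom.length_bp:
        import warnings

        warnings.warn(
            f"bin size {bin_size_bp} exceeds {chrom.name} length; single bin"
        )
    n_bins = max(1, -(-chrom.length_bp // bin_size_bp))  # ceil division
    out = np.zeros(n_bins)
    for s, e, v in zip(track.starts, track.ends, track.values):
        s = max(int(s), 0)
        e = min(int(e), chrom.length_bp)
        if e <= s:
            continue
        width = e - s
        first, last = s // bin_size_bp, (e - 1) // bin_size_bp
        for b in range(first, last + 1):
            lo = max(s, b * bin_size_bp)
            hi = min(e, (b + 1) * bin_size_bp)
            out[b] += v * (hi - lo) / width
    return BinnedDensity(chrom=chrom.name, bin_size_bp=bin_size_bp, values=out)


def write_binned_density(density: BinnedDensity, path) -> None:
    pd.DataFrame(
        {
            "chrom": density.chrom,
            "start": density.starts,
            "end": np.minimum(density.starts + density.bin_size_bp,
                              density.starts[-1] + density.bin_size_bp),
            "value": density.values,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
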