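"""Synthetic study inputs: a Chr19-like chromosome, SSR panels and feature tracks.

These generators emulate the published study conditions — a ~15.9 Mbp
chromosome with a 5.3-6.7 Mbp centromere, 14-87 screened SSR markers with
three marker-free repeat-rich gaps, populations of ~45-85 triploids — with
synthetic feature tracks whose spatial structure mimics the real genome:
methylation and LTR-Gypsy content peak at the centromere, gene density
rises toward the arms, and AT-low-complexity content varies independently.
All values are synthetic; none are measurements.
"""

from __future__ import annotations

import numpy as np

from .genome import ChromosomeModel, FeatureTrack, MarkerLocus, MarkerPanel

#: Chr19-like chromosome: length and centromere interval as in P. trichocarpa v3.0
CHR19_LENGTH_BP = 15_900_000
CHR19_CENTROMERE = (5_300_000, 6_700_000)

#: marker-free segments (repeat-rich / multi-mapping) on the Chr19-like model, bp
CHR19_GAPS = ((600_000, 1_200_000), (5_300_000, 6_700_000), (13_600_000, 14_400_000))


def make_demo_chromosome(name: str = "Chr19") -> ChromosomeModel:
    return ChromosomeModel(
        name=name,
        length_bp=CHR19_LENGTH_BP,
        centromere_start_bp=CHR19_CENTROMERE[0],
        centromere_end_bp=CHR19_CENTROMERE[1],
    )


def make_demo_tracks(
    chrom: ChromosomeModel,
    rng: np.random.Generator | int | None = None,
    bin_size_bp: int = 100_000,
) -> dict[str, FeatureTrack]:
    """Synthetic feature tracks (bedGraph-shaped) over one chromosome.

    Returns one track per kind: methylation (MeDIP-like, centromere-peaked),
    ltr_gypsy (proportion, centromere-peaked), low_complexity (proportion,
    spatially autocorrelated noise), gene_density (genes per bin, arm-
    enriched) and recomb_rate (cM/Mb-like, arm-enriched).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    starts = np.arange(0, chrom.length_bp, bin_size_bp, dtype=np.int64)
    ends = np.minimum(starts + bin_size_bp, chrom.length_bp)
    mids = (starts + ends) / 2.0
    cen_mid = (chrom.centromere_start_bp + chrom.centromere_end_bp) / 2.0
    d = np.abs(mids - cen_mid) / 1e6  # Mbp from centromere midpoint

    def smooth_noise(scale: float, corr_bins: int = 5) -> np.ndarray:
        raw = rng.normal(0.0, 1.0, len(mids) + corr_bins)
        kernel = np.ones(corr_bins) / corr_bins
        return scale * np.convolve(raw, kernel, mode="valid")[: len(mids)]

    methylation = np.clip(
        8.0 + 30.0 * np.exp(-((d / 2.0) ** 2)) + smooth_noise(2.5), 0.0, None
    )
    ltr = np.clip(
        0.05 + 0.40 * np.exp(-((d / 2.5) ** 2)) + smooth_noise(0.04), 0.0, None
    )
    # AT-low-complexity fraction is depleted in the LTR-dominated
    # pericentromere and enriched on the gene-rich arms; regional (multi-Mb)
    # structure matters because hDNA tracts average the landscape over
    # megabase windows
    lowcomp = np.clip(
        0.015 + 0.030 * (1.0 - np.exp(-((d / 3.0) ** 2)))
        + smooth_noise(0.015, corr_bins=15),
        0.0, None,
    )
    gene_density = np.clip(
        22.0 * (1.0 - 0.8 * np.exp(-((d / 3.0) ** 2))) + smooth_noise(2.0), 0.0, None
    )
    recomb = np.clip(1.0 + 2.5 * (1.0 - np.exp(-((d / 3.0) ** 2))) + smooth_noise(0.4),
                     0.0, None)
    payload = {
        "methylation": methylation,
        "ltr_gypsy": ltr,
        "low_complexity": lowcomp,
        "gene_density": gene_density,
        "recomb_rate": recomb,
    }
    return {
        kind: FeatureTrack(chrom=chrom.name, starts=starts, ends=ends,
                           values=vals, kind=kind)
        for kind, vals in payload.items()
    }


def make_demo_panel(
    chrom: ChromosomeModel,
    n_markers: int = 79,
    rng: np.random.Generator | int | None = None,
    gaps: tuple[tuple[int, int], ...] = CHR19_GAPS,
    paternal_het_fraction: float = 0.5,
) -> MarkerPanel:
    """A screened SSR panel with study-like marker placement.

    Marker positions are uniform over the chromosome outside the marker-free
    gaps; every locus is maternally heterozygous with no allele shared with
    the paternal parent (i.e., already screening-eligible), and the paternal
    parent is heterozygous at ``paternal_het_fraction`` of loci.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    positions: set[int] = set()
    while len(positions) < n_markers:
        pos = int(rng.integers(0, chrom.length_bp))
        if any(lo <= pos < hi for lo, hi in gaps):
            continue
        positions.add(pos)
    loci = []
    for i, pos in enumerate(sorted(positions)):
        # distinct fragment sizes in a typical SSR range
        sizes = rng.choice(np.arange(140, 320), size=4, replace=False)
        mat = tuple(int(s) for s in sorted(sizes[:2]))
        n_pat = 2 if rng.random() < paternal_het_fraction else 1
        pat = tuple(int(s) for s in sorted(sizes[2 : 2 + n_pat]))
        loci.append(
            MarkerLocus(
                marker_id=f"SYN{i + 1:04d}",
                chrom=chrom.name,
                pos_bp=pos,
                maternal_alleles=mat,
                paternal_alleles=pat,
            )
        )
    return MarkerPanel(tuple(loci))
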