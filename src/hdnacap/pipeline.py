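"""End-to-end orchestration: simulate -> call -> stats -> correlate.

Each stage consumes the previous stage's files, so stages are independently
runnable (and tested). A run is a pure function of (config, seed): the
aggregated ``report.json`` is byte-identical across reruns; timings go to
the log only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import calling, correlates, restats
from .genome import (
    ChromosomeModel,
    ValidationError,
    load_chromosomes,
    load_marker_panel,
    read_feature_track,
    screen_markers,
    write_marker_panel,
)
from .simulate import (
    LandscapeWeights,
    MeiosisParams,
    TriploidGenotypeTable,
    build_landscape,
    generate_population,
)

logger = logging.getLogger(__name__)


@dataclass
class SimulateBlock:
    n_individuals: int = 83
    missing_rate: float = 0.0
    params: MeiosisParams = field(default_factory=MeiosisParams)
    weights: LandscapeWeights = field(default_factory=LandscapeWeights)


@dataclass
class RunConfig:
    markers: str
    chromosomes: str
    chrom: str
    genotypes: str | None = None
    simulate: SimulateBlock | None = None
    tracks: dict[str, str] = field(default_factory=dict)
    subsample_sizes: tuple[int, ...] = ()
    subsample_reps: int = 30
    genotype_label: str = ""

    def __post_init__(self) -> None:
        if (self.genotypes is None) == (self.simulate is None):
            raise ValidationError(
                "config must name exactly one of: a genotypes file, a simulate block"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        sim = None
        if "simulate" in raw and raw["simulate"] is not None:
            s = dict(raw["simulate"])
            sim = SimulateBlock(
                n_individuals=int(s.get("n_individuals", 83)),
                missing_rate=float(s.get("missing_rate", 0.0)),
                params=MeiosisParams(**s.get("params", {})),
                weights=LandscapeWeights(**s.get("weights", {})),
            )
        return cls(
            markers=raw["markers"],
            chromosomes=raw["chromosomes"],
            chrom=raw["chrom"],
            genotypes=raw.get("genotypes"),
            simulate=sim,
            tracks=dict(raw.get("tracks", {})),
            subsample_sizes=tuple(raw.get("subsample_sizes", ())),
            subsample_reps=int(raw.get("subsample_reps", 30)),
            genotype_label=str(raw.get("genotype_label", "")),
        )

    def canonical(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "markers": self.markers,
            "chromosomes": self.chromosomes,
            "chrom": self.chrom,
            "genotypes": self.genotypes,
            "tracks": dict(sorted(self.tracks.items())),
            "subsample_sizes": list(self.subsample_sizes),
            "subsample_reps": self.subsample_reps,
            "genotype_label": self.genotype_label,
        }
        if self.simulate is not None:
            out["simulate"] = {
                "n_individuals": self.simulate.n_individuals,
                "missing_rate": self.simulate.missing_rate,
                "params": vars(self.simulate.params),
                "weights": {
                    k: v for k, v in vars(self.simulate.weights).items()
                    if not k.startswith("_")
                },
            }
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: RunConfig, seed: int, out_dir: str | Path) -> dict[str, Any]:
    """Run every stage and write all outputs under ``out_dir``; returns the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "seed": int(seed),
        "config_hash": config.config_hash(),
        "config": config.canonical(),
    }

    chroms = load_chromosomes(config.chromosomes)
    if config.chrom not in chroms:
        raise ValidationError(f"chromosome {config.chrom} not in {config.chromosomes}")
    chrom = chroms[config.chrom]
    raw_panel = load_marker_panel(config.markers, require_eligible=False)
    panel, rejected = screen_markers(raw_panel)
    panel = panel.on_chromosome(chrom.name)
    if rejected:
        logger.warning("screened out %d markers: %s", len(rejected), rejected[:5])
    report["markers"] = {
        "n_loaded": len(raw_panel),
        "n_eligible": len(panel),
        "rejected": [list(r) for r in rejected],
    }

    tracks = {
        kind: read_feature_track(path, kind) for kind, path in sorted(config.tracks.items())
    }

    # --- stage: genotypes (load or simulate) -------------------------------
    truth = None
    if config.simulate is not None:
        if not tracks:
            raise ValidationError("simulate block requires feature tracks")
        landscape = build_landscape(
            [t for k, t in tracks.items() if k != "recomb_rate" or
             config.simulate.weights.w_recomb_rate != 0.0],
            chrom, config.simulate.weights,
        )
        rng = np.random.default_rng(seed)
        table, truth = generate_population(
            config.simulate.params, landscape, panel, chrom,
            n_individuals=config.simulate.n_individuals,
            missing_rate=config.simulate.missing_rate, rng=rng,
        )
        table.to_tsv(out / "genotypes.tsv")
        write_marker_panel(panel, out / "markers.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(
                [
                    {
                        "n_events": egg.n_events,
                        "tracts": [
                            [t.start_bp, t.end_bp, t.repaired] for t in egg.tracts
                        ],
                        "genotypes": egg.genotypes,
                    }
                    for egg in truth
                ],
                fh,
            )
        logger.info("simulated %d individuals at %d loci", len(table), len(panel))
    else:
        table = TriploidGenotypeTable.from_tsv(config.genotypes)
    report["population"] = {"n_individuals": len(table), "n_loci": len(table.marker_ids)}

    # --- stage: hDNA calling ----------------------------------------------
    constitutions = calling.classify_table(table, panel)
    hf = calling.hdna_frequency(constitutions, panel)
    calling.write_hdna_frequency(hf, out / "hdna_frequency.tsv")
    defined = hf["HF"].dropna()
    report["hdna"] = {
        "n_loci": int(len(hf)),
        "hf_min": float(defined.min()) if len(defined) else None,
        "hf_max": float(defined.max()) if len(defined) else None,
        "hf_mean": float(defined.mean()) if len(defined) else None,
    }

    # --- stage: RE statistics ----------------------------------------------
    call_matrix = calling.constitutions_to_calls(constitutions)
    counts = restats.count_res_population(call_matrix, panel, chrom)
    pd.DataFrame(
        {
            "individual_id": counts.index,
            "chrom": chrom.name,
            "re_count": counts.to_numpy(),
            "n_markers_used": len(panel),
        }
    ).to_csv(out / "re_counts.tsv", sep="\t", index=False)
    dist = restats.re_distribution(counts)
    stats_block: dict[str, Any] = {
        "mean_re": float(counts.mean()),
        "max_re": int(counts.max()),
        "distribution": {int(k): float(v) for k, v in dist.items()},
    }
    norm = restats.test_normality(counts) if len(counts) >= 5 else None
    if norm is not None:
        stats_block["ks_statistic"] = norm.statistic
        stats_block["ks_p"] = norm.p_value
        stats_block["ks_note"] = norm.note
    if len(dist) >= 4:
        fit = restats.fit_gaussian(dist)
        stats_block["gaussian_fit"] = fit.as_dict()
    if config.subsample_sizes:
        scheme = restats.SubsampleScheme(
            sizes=tuple(config.subsample_sizes), reps=config.subsample_reps, seed=seed
        )
        summary, _ = restats.subsample_analysis(call_matrix, panel, chrom, scheme)
        stats_block["subsample"] = summary.to_dict(orient="records")
        if len(summary) >= 3:
            reg = restats.regress_xc_vs_nmarkers(
                list(zip(summary["size"], summary["mean_xc"]))
            )
            stats_block["xc_vs_nmarkers"] = {
                "slope": reg.slope, "intercept": reg.intercept,
                "R2": reg.r_squared, "p": reg.p_value,
            }
    report["re_stats"] = stats_block
    with open(out / "fits.json", "w") as fh:
        json.dump(_round_floats(stats_block), fh, indent=1, sort_keys=True)

    # --- stage: genomic correlates ----------------------------------------
    corr_tracks = {k: t for k, t in tracks.items() if k != "gene_density"} | (
        {"gene_density": tracks["gene_density"]} if "gene_density" in tracks else {}
    )
    corr = correlates.correlation_table(
        hf, corr_tracks, panel, chrom, genotype=config.genotype_label
    )
    corr.to_csv(out / "correlations.tsv", sep="\t", index=False, float_format="%.6g")
    report["correlations"] = _round_floats(corr.to_dict(orient="records"))
    if "gene_density" in tracks:
        density = correlates.bin_gene_density(tracks["gene_density"], chrom, 500_000)
        correlates.write_binned_density(density, out / "density.tsv")
        report["gene_density_bins"] = len(density.values)

    report = _round_floats(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    logger.info("report written to %s", out / "report.json")
    return report
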