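"""End-to-end experiments: the phenotype time-scale reanalysis and the
coldspot/background-selection experiment, with reproducible manifests.

Each pipeline takes a master seed; per-stage and per-replicate seeds are
derived through :func:`evoscales.synthetic_data.substream_seeds`, so a run is
reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import forward_sim as fs
from . import pheno_trends as pt
from . import popgen_stats as ps
from .io import write_track
from .synthetic_data import substream_seeds

__all__ = [
    "run_pheno_reanalysis",
    "replicate_scan_tracks",
    "run_coldspot_experiment",
    "write_manifest",
]


def write_manifest(outdir: Path, config: dict, seed: int, stage_seeds=None) -> Path:
    manifest = {
        "tool": "evoscales",
        "version": __version__,
        "master_seed": seed,
        "stage_seeds": stage_seeds,
        "config": config,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


# ---------------------------------------------------------------------------
# phenotype reanalysis
# ---------------------------------------------------------------------------


def run_pheno_reanalysis(
    data: pd.DataFrame,
    trait: str = "bill",
    covariate: str = "tarsus",
    n_perm: int = 10_000,
    seed: int = 0,
    outdir: str | Path | None = None,
    early_years: set[int] | None = None,
) -> dict:
    """Full time-scale analysis of one phenotype series.

    Steps: annual summaries; maximally selected breakpoint; Welch t across
    the detected cut; linear trends over the full range and the post-cut
    range for the trait (with and without the covariate), the covariate
    itself, and the trait/covariate ratio; the consecutive-year slope scan;
    and a LOESS smooth of annual means.  Returns a result bundle dict and
    optionally writes TSV/JSON reports.
    """
    for col in ("year", "bill_mm"):
        if col not in data.columns:
            raise ValueError(f"phenotype table is missing column {col!r}")
    bundle: dict = {"trait": trait, "seed": seed}
    summaries = pt.annual_summaries(data, trait)
    bundle["annual_summaries"] = summaries

    bp = pt.max_sel_breakpoint(data, trait, n_perm=n_perm, seed=seed)
    bundle["breakpoint"] = bp
    cut_year = bp.best_cut[0]

    vals = pt.trait_values(data, trait)
    pre = vals[data["year"] <= cut_year]
    post = vals[data["year"] > cut_year]
    if pre.size >= 2 and post.size >= 2 and bp.maxT > 0:
        bundle["welch_pre_post"] = pt.welch_t_test(pre, post)

    years = data["year"]
    full = (int(years.min()), int(years.max()))
    post_range = (int(bp.best_cut[1]), full[1])
    trends = {}
    for label, rng_ in (("full", full), ("post_cut", post_range)):
        trends[f"{label}_{trait}"] = pt.fit_linear_trend(data, trait, *rng_)
        try:
            trends[f"{label}_{trait}_with_{covariate}"] = pt.fit_linear_trend(
                data, trait, *rng_, covariate=covariate
            )
            trends[f"{label}_{covariate}"] = pt.fit_linear_trend(
                data, covariate, *rng_
            )
            trends[f"{label}_ratio"] = pt.fit_linear_trend(data, "ratio", *rng_)
        except (KeyError, ValueError):
            pass
    bundle["trends"] = trends

    bundle["slope_scan"] = pt.slope_scan(data, trait, early_years=early_years)
    bundle["loess_annual_means"] = pd.DataFrame(
        {
            "year": summaries["year"],
            "mean": summaries["mean"],
            "loess": pt.loess_smooth(summaries["year"], summaries["mean"]),
        }
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summaries.to_csv(outdir / "annual_summaries.tsv", sep="\t", index=False)
        bp.per_cut.to_csv(outdir / "breakpoint_per_cut.tsv", sep="\t", index=False)
        bundle["slope_scan"].windows.to_csv(
            outdir / "slope_scan.tsv", sep="\t", index=False
        )
        bundle["loess_annual_means"].to_csv(
            outdir / "loess_annual_means.tsv", sep="\t", index=False
        )
        summary = {
            "trait": trait,
            "breakpoint": {
                "best_cut": list(bp.best_cut),
                "maxT": bp.maxT,
                "p": bp.p,
                "n_perm": bp.n_perm,
            },
            "welch_pre_post": dataclasses.asdict(bundle["welch_pre_post"])
            if "welch_pre_post" in bundle
            else None,
            "trends": {k: dataclasses.asdict(v) for k, v in trends.items()},
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        write_manifest(
            outdir, {"trait": trait, "covariate": covariate, "n_perm": n_perm}, seed
        )
    return bundle


# ---------------------------------------------------------------------------
# coldspot experiment
# ---------------------------------------------------------------------------

CONTRAST_DIRECTIONS = {
    # statistic -> expected sign of (coldspot - flanks) under background
    # selection in a recombination coldspot
    "pi": -1,
    "long_distance_r2": +1,
    "ies": +1,
    "eigengwas_logp": +1,
}


def replicate_scan_tracks(
    sample: fs.SimSample,
    pi_window: int = 200_000,
    pi_step: int = 50_000,
    ld_window: int = 200_000,
    ld_step: int = 50_000,
    min_sep: int = 20_000,
    max_sep: int = 200_000,
    min_maf: float = 0.05,
    smooth: bool = True,
    smooth_window: float | None = None,
) -> dict[str, ps.ScanTrack]:
    """All Figure-style tracks for one simulated sample.

    Returns tracks keyed pi, long_distance_r2, ies, eigengwas_logp (the
    -log10 genomic-control-corrected p per SNP).  The LOESS smoothing
    window defaults to 1/20 of the chromosome (1 Mb on a 20 Mb chromosome)
    so it scales together with the rest of a scaled-down experiment.
    """
    hm = sample.haplotypes
    tracks: dict[str, ps.ScanTrack] = {}
    tracks["pi"] = ps.pi_windows(hm, window=pi_window, step=pi_step)
    tracks["long_distance_r2"] = ps.long_distance_ld_track(
        hm, window=ld_window, step=ld_step, min_sep=min_sep, max_sep=max_sep,
        min_maf=min_maf,
    )
    tracks["ies"] = ps.ies_scan(hm)
    gm = hm.to_genotypes()
    eg = ps.eigengwas_scan(gm, min_maf=min_maf)
    logp = -np.log10(np.clip(eg.p_gc, 1e-300, None))
    tracks["eigengwas_logp"] = ps.ScanTrack(
        "eigengwas_logp", eg.positions.astype(float), logp, chrom=hm.chrom,
        meta={"lambda_gc": eg.lambda_gc},
    )
    if smooth:
        if smooth_window is None:
            smooth_window = hm.length / 20
        for k in list(tracks):
            try:
                tracks[k] = ps.smooth_track(tracks[k], target_window=smooth_window)
            except ValueError:
                pass
    return tracks


def run_coldspot_experiment(
    params: fs.ForwardSimParams | None = None,
    n_replicates: int = 10,
    seed: int = 0,
    deleterious: bool = True,
    flank_margin: int = 200_000,
    outdir: str | Path | None = None,
    ld_decay: bool = False,
    track_kwargs: dict | None = None,
) -> dict:
    """Simulate replicates of a coldspot chromosome and contrast the scan
    statistics inside vs outside the coldspot.

    With ``params=None`` the desk-scale preset is used (5 Mb chromosome,
    central 400 kb coldspot at 1% recombination, Q = 10 rescaling; the
    deleterious fraction is 0.3 when ``deleterious`` else 0).  Returns a
    bundle with per-replicate contrast ratios and the across-replicate sign
    summary.
    """
    if params is None:
        params = fs.desk_scale_params(deleterious=deleterious, seed=seed)
    coldspot = fs.desk_coldspot_interval(params)
    rep_seeds = substream_seeds(seed, n_replicates)
    rows = []
    failures = []
    tracks_per_rep = []
    for r, rs in enumerate(rep_seeds):
        p = dataclasses.replace(params, seed=rs)
        try:
            sample = fs.run_simulation(p)
            tracks = replicate_scan_tracks(sample, **(track_kwargs or {}))
            contrasts = fs.coldspot_contrast(
                tracks, coldspot, flank_margin, use_smoothed=("eigengwas_logp",)
            )
            row = {"replicate": r, "seed": rs, "n_sites": sample.haplotypes.n_sites}
            for name, c in contrasts.items():
                row[f"{name}_inside"] = c.inside_mean
                row[f"{name}_outside"] = c.outside_mean
                row[f"{name}_ratio"] = c.ratio
            if ld_decay:
                tracks["ld_decay"] = ps.ld_decay_curve(sample.haplotypes)
            rows.append(row)
            tracks_per_rep.append(tracks)
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            failures.append({"replicate": r, "seed": rs, "error": str(exc)})
    table = pd.DataFrame(rows)
    signs = {}
    for name, direction in CONTRAST_DIRECTIONS.items():
        col = f"{name}_ratio"
        if col in table:
            ok = (table[col] < 1) if direction < 0 else (table[col] > 1)
            signs[name] = {
                "expected": "coldspot lower" if direction < 0 else "coldspot higher",
                "n_in_direction": int(ok.sum()),
                "n_replicates": int(table.shape[0]),
                "mean_ratio": float(table[col].mean()),
            }
    bundle = {
        "params": params,
        "coldspot": coldspot,
        "replicates": table,
        "sign_summary": signs,
        "failures": failures,
        "tracks": tracks_per_rep,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "replicate_contrasts.tsv", sep="\t", index=False)
        for r, tracks in enumerate(tracks_per_rep):
            for name, tr in tracks.items():
                write_track(tr, outdir / f"rep{r}_{name}.tsv")
        (outdir / "sign_summary.json").write_text(json.dumps(signs, indent=2))
        write_manifest(
            outdir,
            {
                "params": dataclasses.asdict(params),
                "n_replicates": n_replicates,
                "deleterious": deleterious,
                "flank_margin": flank_margin,
            },
            seed,
            rep_seeds,
        )
    return bundle
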