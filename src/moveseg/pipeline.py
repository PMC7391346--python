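"""End-to-end orchestration: ingest -> regularize -> summarize -> HMM -> post hoc.

All defaults match the study settings: 6-hr intervals, 100 imputations,
3 states, 25 optimizer starts, 75% isopleths. One root seed derives the
per-stage seeds by fixed offsets so a run is reproducible from the config
alone.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from . import hmm as hmm_mod
from . import ingest_io, regularization, space_use, summarization

STAGE_SEED_OFFSETS = {"regularize": 101, "imputation": 211, "hmm": 307, "simulate": 401}


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    argos_path: str = ""
    dive_path: str = ""
    profile_path: str = ""
    haulout_path: str = ""
    bathymetry_path: str = ""
    out_dir: str = "out"
    interval_h: float = 6.0
    n_sims: int = 100
    n_states: int = 3
    n_starts: int = 25
    seed: int = 42
    ellipse_scale: float = 1.0
    isopleth_level: float = 0.75
    coast_bin_km: float = 10.0
    depth_bin_m: float = 400.0
    exclude_hours: float = 24.0
    exclude_animals: tuple = ()

    def stage_seed(self, stage: str) -> int:
        return (self.seed + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def _fmt_matrix(m: np.ndarray, labels) -> str:
    head = "\t" + "\t".join(labels)
    rows = [head]
    for lab, row in zip(labels, m):
        rows.append(lab + "\t" + "\t".join(f"{v:.2f}" for v in row))
    return "\n".join(rows)


def records_from_imputation(track_xy: np.ndarray, times: np.ndarray, animal_id: str,
                            dives, profiles, haulouts, center_lon, center_lat,
                            interval_h: float = 6.0) -> pd.DataFrame:
    """Interval records for one imputed (or smoothed) planar track."""
    from . import geo

    lon, lat = geo.unproject_aeqd(track_xy[:, 0], track_xy[:, 1], center_lon, center_lat)
    track = pd.DataFrame({"animal_id": animal_id, "time": times, "lon": lon, "lat": lat})
    return summarization.bin_intervals(track, dives, profiles, haulouts, interval_h)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write stage outputs plus a run report.

    Returns a dict with the principal objects (records, fit, decoded
    states, budgets, home ranges). Any stage error aborts with the stage
    name; outputs written before the failure are preserved.
    """
    from . import geo

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: list[str] = [f"moveseg run (seed {config.seed})", ""]
    result: dict = {}
    stage = "ingest"
    try:
        argos = ingest_io.read_argos(config.argos_path)
        dives, profiles, haulouts = ingest_io.read_dives_profiles_haulouts(
            config.dive_path, config.profile_path, config.haulout_path
        )
        bathy = ingest_io.read_bathymetry(config.bathymetry_path) if config.bathymetry_path else None
        for aid in config.exclude_animals:
            argos = argos[argos["animal_id"] != aid]
        animals = list(dict.fromkeys(argos["animal_id"]))
        report.append(f"ingest: {len(argos)} fixes, {len(dives)} dives, {len(animals)} animals")

        stage = "regularize"
        tracks = {}
        imputations = {}
        for aid in animals:
            fx = argos[argos["animal_id"] == aid]
            params = regularization.fit_ctcrw(fx, ellipse_scale=config.ellipse_scale)
            tr = regularization.predict_regular(params, fx, config.interval_h,
                                                ellipse_scale=config.ellipse_scale)
            tracks[aid] = tr
            if config.n_sims > 1:
                imputations[aid] = regularization.draw_imputations(
                    params, fx, config.n_sims, seed=config.stage_seed("imputation"),
                    interval_h=config.interval_h, ellipse_scale=config.ellipse_scale,
                )
            report.append(
                f"regularize {aid}: beta={params.beta:.3g}/h sigma={params.sigma:.3g} "
                f"loglik={params.loglik:.1f} (ellipse axes treated as {config.ellipse_scale}-sigma)"
            )
        pd.concat([t.to_frame() for t in tracks.values()]).to_csv(out / "tracks.csv", index=False)

        stage = "summarize"
        def summarize_tracks(xy_by_animal):
            recs = []
            for aid, (xy, times) in xy_by_animal.items():
                recs.append(records_from_imputation(
                    xy, times, aid, dives, profiles, haulouts,
                    geo.STUDY_CENTER_LON, geo.STUDY_CENTER_LAT, config.interval_h))
            rec = pd.concat(recs, ignore_index=True)
            return summarization.exclude_initial(rec, config.exclude_hours)

        mean_records = summarize_tracks(
            {aid: (np.column_stack([t.x_km, t.y_km]), t.times) for aid, t in tracks.items()}
        )
        mean_records.to_csv(out / "records.csv", index=False)
        result["records"] = mean_records

        stage = "fit"
        spec = hmm_mod.HMMSpec(n_states=config.n_states)
        if config.n_sims > 1:
            fits = []
            init = None
            for k in range(config.n_sims):
                rec_k = summarize_tracks(
                    {aid: (imputations[aid].draws[k], imputations[aid].times) for aid in animals}
                )
                fit_k = hmm_mod.fit_hmm(
                    spec, rec_k,
                    n_starts=config.n_starts if k == 0 else 1,
                    seed=config.stage_seed("hmm") + k,
                    init=init,
                )
                init = {"emissions": fit_k.emissions, "tpm": fit_k.tpm, "delta": fit_k.delta}
                fits.append(fit_k)
            pooled = hmm_mod.pool_mi_fits(fits)
            fit = fits[0]
            fit.emissions, fit.tpm, fit.delta = pooled["emissions"], pooled["tpm"], pooled["delta"]
            result["mi_pooled"] = pooled
            report.append(f"fit: pooled over {config.n_sims} imputations")
        else:
            fit = hmm_mod.fit_hmm(spec, mean_records, n_starts=config.n_starts,
                                  seed=config.stage_seed("hmm"))
        result["fit"] = fit
        labels = list(spec.state_labels or [f"state{i+1}" for i in range(spec.n_states)])
        report += ["", "Transition probability matrix:", _fmt_matrix(fit.tpm, labels), ""]
        for name, p in fit.emissions.items():
            report.append(f"{name}: " + "; ".join(
                f"{k}=[{', '.join(f'{v:.3f}' for v in vals)}]" for k, vals in p.items()))
        report.append(f"loglik={fit.loglik:.2f} AIC={fit.aic:.2f}")
        with open(out / "fit.json", "w") as fh:
            json.dump(
                {
                    "emissions": {n: {k: list(v) for k, v in p.items()} for n, p in fit.emissions.items()},
                    "tpm": fit.tpm.tolist(),
                    "delta": fit.delta.tolist(),
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                    "n_free_params": fit.spec.n_free_params,
                    "start_logliks": fit.start_logliks,
                    "seed": fit.seed,
                    "state_labels": labels,
                },
                fh, indent=1,
            )

        stage = "decode"
        seq = hmm_mod.local_state_probs(fit, mean_records)
        decoded = mean_records.assign(
            state=seq.viterbi, diving_prob=seq.merged_diving_prob
        )
        pos = pd.concat(
            [t.to_frame()[["animal_id", "time", "lon", "lat"]] for t in tracks.values()],
            ignore_index=True,
        )
        decoded = decoded.merge(pos, on=["animal_id", "time"], how="left")
        decoded.to_csv(out / "decoded.csv", index=False)
        result["decoded"] = decoded

        stage = "covariates"
        has_temp = decoded["temp_median_C"].notna()
        if has_temp.sum() >= 30 and decoded.loc[has_temp, "state"].nunique() >= 2:
            try:
                mfit = cov.fit_multinomial(decoded.loc[has_temp, "state"],
                                           decoded.loc[has_temp, "temp_median_C"])
                result["multinomial"] = mfit
                report.append("multinomial state~temperature slopes: "
                              + ", ".join(f"{b:.3f}(se {s:.3f})" for b, s in zip(mfit.coef[:, 1], mfit.se[:, 1])))
            except (RuntimeError, ValueError) as e:
                report.append(f"multinomial regression skipped: {e}")
        if bathy is not None:
            d2c, _ = cov.distance_to_coast(decoded["lon"], decoded["lat"], bathy)
            depth = -np.atleast_1d(bathy.value_at(decoded["lon"], decoded["lat"]))
            result["coast_budget"] = cov.activity_budget(decoded["state"], d2c, config.coast_bin_km)
            sea = depth > 0
            result["depth_budget"] = cov.activity_budget(decoded["state"][sea], depth[sea], config.depth_bin_m)
            result["coast_budget"].to_frame().to_csv(out / "budget_coast.csv", index=False)
            result["depth_budget"].to_frame().to_csv(out / "budget_depth.csv", index=False)

        stage = "space_use"
        grids = {}
        areas = {}
        for aid, t in tracks.items():
            xy = np.column_stack([t.x_km, t.y_km])
            if len(xy) >= 30:
                g = space_use.kde_density(xy)
                grids[aid] = g
                areas[aid] = space_use.isopleth(g, config.isopleth_level).area_km2
        if grids:
            ov = space_use.overlap_matrix(grids)
            ov.to_csv(out / "overlap.csv")
            pd.Series(areas, name=f"area_{int(config.isopleth_level*100)}pct_km2").to_csv(out / "homerange.csv")
            result["areas_km2"] = areas
            result["overlap"] = ov
            report.append(f"mean {int(config.isopleth_level*100)}% isopleth area: "
                          f"{np.mean(list(areas.values())):.0f} km^2 over {len(areas)} animals")
    except Exception as e:
        (out / "report.txt").write_text("\n".join(report) + f"\n\nFAILED at stage {stage}: {e}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e
    (out / "report.txt").write_text("\n".join(report) + "\n")
    result["report"] = "\n".join(report)
    return result
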