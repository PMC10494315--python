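"""End-to-end orchestration: scans -> structure -> ordination -> gradient
forest -> SDM -> genomic-niche integration.

One :class:`RunConfig` (YAML/JSON-loadable) drives the whole chain, per
future scenario, with per-stage seeds derived by stable hashing of the
master seed and stage name.  Every stage writes its artifacts into the
output directory and the run ends with a manifest of files and
checksums.  Inputs are either file paths (genotypes, env tables, grids,
occurrences) or a synthetic-landscape block that generates the study
in-memory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gforest, integrate, ordination, scan, sdm, structure, synthdata
from .io import EnvTable, log, read_env_table, read_genotypes, read_occurrences

STAGES = ("data", "scan", "structure", "ordination", "gforest", "sdm", "integrate")


class ValidationError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated run configuration.

    Exactly one of ``synthetic`` (landscape parameters) or the file-path
    block (``genotypes``/``env_present``/``grid_present``/...) must be
    provided.  ``scenarios`` maps each future-scenario name to either a
    grid CSV path (file mode) or a driver-shift multiplier (synthetic
    mode).
    """

    out_dir: str
    seed: int = 0
    scenarios: dict = field(default_factory=lambda: {"future": 1.0})
    synthetic: dict | None = None
    genotypes: str | None = None
    genotype_format: str = "csv012"
    env_present: str | None = None
    grid_present: str | None = None
    occurrences: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.scenarios)) != len(self.scenarios):
            raise ValidationError("scenario names must be unique")
        if self.synthetic is None:
            missing = [
                name
                for name in ("genotypes", "env_present", "grid_present", "occurrences")
                if getattr(self, name) is None
            ]
            if missing:
                raise ValidationError(f"config missing required input fields: {missing}")
            paths = [self.genotypes, self.env_present, self.grid_present, self.occurrences]
            paths += [p for p in self.scenarios.values() if isinstance(p, str)]
            absent = [p for p in paths if not Path(p).exists()]
            if absent:
                raise ValidationError(f"referenced files do not exist: {absent}")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        text = Path(path).read_text()
        if path.endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls(**raw)


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (master * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _default_params() -> dict:
    return {
        "maf_min": 0.05,
        "scan_K": 5,
        "lfmm_replicates": 5,
        "z_min": 2.0,
        "q_max": 0.05,
        "env_cum_var": 0.90,
        "snmf_K_max": 4,
        "snmf_replicates": 5,
        "rda_alpha": 0.05,
        "rda_n_perm": 199,
        "r_max": 0.70,
        "gf_n_trees": 100,
        "gf_corr_threshold": 0.50,
        "sdm_feature_sets": (("linear",), ("linear", "quadratic", "hinge")),
        "sdm_multipliers": (1.0, 2.0),
        "buffer_km": 1000.0,
        "n_background": 1000,
        "alpha": None,
        "objective": "l2",
    }


def _load_inputs(cfg: RunConfig):
    """Materialize the dataset from files or the synthetic generator."""
    if cfg.synthetic is not None:
        lc_kwargs = dict(cfg.synthetic)
        lc_kwargs.setdefault("seed", stage_seed(cfg.seed, "data"))
        lc = synthdata.LandscapeConfig(**lc_kwargs)
        ds = synthdata.simulate_dataset(lc)
        grids_future = {}
        for name, shift in cfg.scenarios.items():
            lc_s = dataclasses.replace(lc, future_shift=float(shift) * lc.future_shift)
            grids_future[name] = synthdata.project_future(ds.grid_present, lc_s, name)
        return ds.genotypes, ds.env_present, ds.grid_present, grids_future, ds.occurrences
    gm = read_genotypes(cfg.genotypes, cfg.genotype_format)
    env_present = read_env_table(cfg.env_present, "present")
    grid_present = read_env_table(cfg.grid_present, "present")
    grids_future = {
        name: read_env_table(path, name) for name, path in cfg.scenarios.items()
    }
    occ = read_occurrences(cfg.occurrences)
    # attach site coordinates from the env table when absent
    if len(gm.site_coords) <= 1 and "site" in env_present.data.columns:
        gm.site_coords = env_present.data[["site", "lon", "lat"]].copy()
        if set(gm.site_labels) - set(gm.site_coords["site"]):
            raise ValidationError("genotype site labels missing from env table")
    return gm, env_present, grid_present, grids_future, occ


def run_pipeline(cfg: RunConfig, stop_after: str | None = None) -> dict:
    """Execute the pipeline and return the manifest.

    Stages run in order (``data, scan, structure, ordination, gforest,
    sdm, integrate``); ``stop_after`` truncates the run after the named
    stage.  Each stage's outputs are written under ``cfg.out_dir`` and
    recorded with SHA-256 checksums; a stage failure raises
    :class:`StageError` and the manifest on disk marks completed stages.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValidationError(f"unknown stage {stop_after!r}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {**_default_params(), **cfg.params}
    manifest: dict = {"stages": [], "files": {}, "seed": cfg.seed, "counts": {}}

    def record(name: str, path: Path):
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    def finish_stage(name: str):
        manifest["stages"].append(name)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    results: dict = {"params": params}

    # ---- data
    try:
        gm, env_present, grid_present, grids_future, occ = _load_inputs(cfg)
    except Exception as exc:
        raise StageError("data", exc) from exc
    manifest["counts"]["individuals"] = gm.n_individuals
    manifest["counts"]["loci_in"] = gm.n_loci
    finish_stage("data")
    if stop_after == "data":
        return manifest

    predictors = list(env_present.predictors)

    # ---- scan
    try:
        gm_f = scan.filter_maf(gm, params["maf_min"])
        K = min(params["scan_K"], gm_f.n_individuals - 2, len(gm_f.sites) - 1)
        K = max(K, 1)
        pca_res = scan.pcadapt_scan(gm_f, K=K, q_max=params["q_max"])
        env_pcs_site, _, _ = scan.env_pca_retain(
            env_present.data, predictors, params["env_cum_var"]
        )
        env_pcs_site["site"] = env_present.data["site"].to_numpy()
        env_pcs = scan.broadcast_env_to_individuals(
            gm_f, env_pcs_site, [c for c in env_pcs_site.columns if c != "site"]
        )
        lfmm_res = scan.lfmm_scan(
            gm_f,
            env_pcs,
            K=K,
            replicates=params["lfmm_replicates"],
            z_min=params["z_min"],
            q_max=params["q_max"],
            seed=stage_seed(cfg.seed, "scan"),
        )
        adaptive, union_report = scan.union_adaptive(pca_res, lfmm_res)
        if not adaptive:
            raise ValueError("no adaptive loci detected")
        pd.concat(
            [pca_res.table.assign(method="pcadapt"), lfmm_res.table.assign(method="lfmm")]
        ).to_csv(out / "scan.csv", index=False)
        record("scan", out / "scan.csv")
        manifest["counts"].update(
            loci_maf=gm_f.n_loci,
            pcadapt=len(pca_res.adaptive),
            lfmm=len(lfmm_res.adaptive),
            adaptive_union=union_report["union"],
        )
    except Exception as exc:
        raise StageError("scan", exc) from exc
    results.update(pcadapt=pca_res, lfmm=lfmm_res, adaptive=adaptive)
    finish_stage("scan")
    keep = [l in adaptive for l in gm_f.locus_ids]
    gm_adapt = gm_f.subset_loci(np.array(keep))
    if stop_after == "scan":
        return manifest

    # ---- structure
    try:
        adm = structure.snmf_admixture(
            gm_adapt,
            K_range=range(1, params["snmf_K_max"] + 1),
            replicates=params["snmf_replicates"],
            seed=stage_seed(cfg.seed, "structure"),
        )
        labels = structure.assign_clusters(adm.Q, gm_adapt)
        pd.DataFrame(adm.Q, index=gm_adapt.individual_ids).to_csv(out / "admixture_q.csv")
        adm.cross_entropy.to_csv(out / "cross_entropy.csv", index=False)
        pd.DataFrame(
            {"individual": gm_adapt.individual_ids, "cluster": labels}
        ).to_csv(out / "clusters.csv", index=False)
        for name in ("admixture_q", "cross_entropy", "clusters"):
            record(name, out / f"{name}.csv")
        manifest["counts"]["chosen_K"] = adm.chosen_K
    except Exception as exc:
        raise StageError("structure", exc) from exc
    results.update(admixture=adm, cluster_labels=labels)
    finish_stage("structure")
    if stop_after == "structure":
        return manifest

    # site-level cluster label (majority vote) used downstream
    site_cluster = (
        pd.DataFrame({"site": gm_adapt.site_labels, "cluster": labels})
        .groupby("site")["cluster"]
        .agg(lambda s: s.mode().iloc[0])
    )

    # ---- ordination
    try:
        freqs = gm_adapt.allele_freq_by_site().fillna(0.0)
        hell = ordination.hellinger_transform(freqs)
        site_coords = env_present.data[["site", "lon", "lat"]].set_index("site").loc[hell.index]
        pcnm, _ = ordination.pcnm_eigenvectors(site_coords.reset_index())
        Xcand = env_present.data.set_index("site").loc[hell.index, predictors].reset_index(drop=True)
        retained, dropped = ordination.collinearity_filter(Xcand, predictors, params["r_max"])
        Xfs = pd.concat([Xcand[retained].reset_index(drop=True), pcnm.reset_index(drop=True)], axis=1)
        rda = ordination.rda_forward_select(
            hell.reset_index(drop=True),
            Xfs,
            alpha=params["rda_alpha"],
            n_perm=params["rda_n_perm"],
            seed=stage_seed(cfg.seed, "ordination"),
        )
        (out / "rda.json").write_text(
            json.dumps(
                {
                    "selected": rda.selected,
                    "step_p": rda.step_pvalues,
                    "r2": rda.r2,
                    "r2_adj": rda.r2_adj,
                    "model_p": rda.model_p,
                    "collinearity_dropped": dropped,
                },
                indent=2,
            )
        )
        record("rda", out / "rda.json")
    except Exception as exc:
        raise StageError("ordination", exc) from exc
    results.update(rda=rda, retained_predictors=retained, pcnm=pcnm, freqs=freqs)
    finish_stage("ordination")
    if stop_after == "ordination":
        return manifest

    # ---- gradient forest
    try:
        gf_predictors = retained
        gf = gforest.fit_gradient_forest(
            freqs,
            Xcand[gf_predictors],
            n_trees=params["gf_n_trees"],
            corr_threshold=params["gf_corr_threshold"],
            seed=stage_seed(cfg.seed, "gforest"),
        )
        offsets = {}
        for name, grid_f in grids_future.items():
            surf = gforest.genomic_offset(gf, grid_present, grid_f)
            surf["scenario"] = name
            surf.to_csv(out / f"offset_{name}.csv", index=False)
            record(f"offset_{name}", out / f"offset_{name}.csv")
            offsets[name] = surf
        gf_dump = {
            "overall_importance": gf.overall_importance.to_dict(),
            "n_kept": len(gf.kept_loci),
            "curves": {
                q: {"x": c.x.tolist(), "y": c.y.tolist()} for q, c in gf.curves.items()
            },
        }
        (out / "gf_model.json").write_text(json.dumps(gf_dump))
        record("gf_model", out / "gf_model.json")
        manifest["counts"]["gf_kept_loci"] = len(gf.kept_loci)
    except Exception as exc:
        raise StageError("gforest", exc) from exc
    results.update(gf=gf, offsets=offsets)
    finish_stage("gforest")
    if stop_after == "gforest":
        return manifest

    # ---- sdm
    try:
        pres, bg = sdm.prepare_occurrences(
            occ,
            grid_present,
            buffer_km=params["buffer_km"],
            n_background=params["n_background"],
            seed=stage_seed(cfg.seed, "sdm"),
        )
        model, board = sdm.tune_select(
            pres,
            bg,
            predictors,
            feature_sets=params["sdm_feature_sets"],
            multipliers=params["sdm_multipliers"],
            seed=stage_seed(cfg.seed, "sdm"),
        )
        board.to_csv(out / "sdm_leaderboard.csv", index=False)
        record("sdm_leaderboard", out / "sdm_leaderboard.csv")
        changes = {}
        for name, grid_f in grids_future.items():
            ch = sdm.binarize_and_change(model, grid_present, grid_f, background=bg)
            df = grid_present.data[["cell_id", "lon", "lat"]].copy()
            df["suitability_present"] = ch["suitability_present"]
            df["suitability_future"] = ch["suitability_future"]
            df["delta_s"] = ch["delta_s"]
            df["scenario"] = name
            df.to_csv(out / f"suitability_{name}.csv", index=False)
            record(f"suitability_{name}", out / f"suitability_{name}.csv")
            changes[name] = ch
        manifest["counts"]["presences"] = len(pres)
    except Exception as exc:
        raise StageError("sdm", exc) from exc
    results.update(sdm_model=model, leaderboard=board, changes=changes, background=bg)
    finish_stage("sdm")
    if stop_after == "sdm":
        return manifest

    # ---- integrate
    try:
        coast = grid_present.data["coast"].to_numpy(float) if "coast" in grid_present.data else None
        if coast is not None:
            cell_cluster = np.where(coast >= np.median(coast), "north", "south")
        else:
            # nearest sampled site's cluster
            sc = env_present.data[["site", "lon", "lat"]]
            D = ordination.haversine_matrix(
                np.concatenate([grid_present.data["lon"], sc["lon"]]),
                np.concatenate([grid_present.data["lat"], sc["lat"]]),
            )[: len(grid_present.data), len(grid_present.data):]
            nearest = np.argmin(D, axis=1)
            cell_cluster = site_cluster.loc[sc["site"].to_numpy()[nearest]].to_numpy()
        comparisons_values, comparisons_labels = {}, {}
        reports = {}
        for name in grids_future:
            surf = integrate.build_risk_surface(
                changes[name]["delta_s"],
                offsets[name]["offset"].to_numpy(),
                cell_cluster,
                alpha=params["alpha"],
                seed=stage_seed(cfg.seed, "integrate"),
                objective=params["objective"],
                cell_meta=grid_present.data[["cell_id", "lon", "lat"]],
            )
            surf.to_csv(out / f"risk_{name}.csv", index=False)
            record(f"risk_{name}", out / f"risk_{name}.csv")
            reports[name] = integrate.risk_report(surf)
            for stat in ("A", "B", "C"):
                key = f"{name}:{stat}"
                comparisons_values[key] = surf[stat].to_numpy()
                comparisons_labels[key] = surf["cluster"].to_numpy()
            comparisons_values[f"{name}:offset"] = offsets[name]["offset"].to_numpy()
            comparisons_labels[f"{name}:offset"] = cell_cluster
        comp = integrate.compare_clusters(comparisons_values, comparisons_labels)
        comp.table.to_csv(out / "comparisons.csv", index=False)
        record("comparisons", out / "comparisons.csv")
    except Exception as exc:
        raise StageError("integrate", exc) from exc
    results.update(risk_reports=reports, comparisons=comp)
    finish_stage("integrate")
    manifest["results"] = {
        name: {
            "alpha": float(reports[name]["ranked"]["alpha"].iloc[0]),
            "cluster_means": reports[name]["cluster_means"],
            "highest_risk_cluster": reports[name]["highest_risk_cluster"],
        }
        for name in reports
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.info("pipeline complete: %d stages, outputs in %s", len(manifest["stages"]), out)
    results["manifest"] = manifest
    return results
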