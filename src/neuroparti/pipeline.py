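"""End-to-end orchestration: simulate -> adjust -> fit -> enrich -> maps -> compare.

A single :class:`RunConfig` (typically parsed from YAML) drives the whole
analysis.  All randomness derives from one root seed through named
substreams, so each stage is reproducible in isolation, and every numeric
output embeds the seed and a hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compositions as comp_mod
from . import enrichment as enr_mod
from . import group_compare as grp_mod
from . import synthetic_data as syn_mod
from .archetype_maps import ComponentMaps, weighted_map
from .compositions import (AdjustedTable, CompositionTable, ConfoundTable,
                           adjust_confounds, impute_median, read_table,
                           write_table)
from .polytope_fit import (bootstrap_archetypes, distances_to_archetypes,
                           fit_archetypes, t_ratio_test)

__all__ = ["RunConfig", "run_pipeline", "validate_tables", "substream_seed"]


def substream_seed(root_seed: int, name: str) -> int:
    """Stable per-stage seed below 2**31 derived from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "neuroparti_run"
    seed: int = 0
    k: int = 3
    n_shuffles: int = 1000
    n_boot: int = 1000
    n_surrogates: int = 1000
    n_bins: int = 10
    q_enrich: float = 0.1
    q_posthoc: float = 0.05
    penalty: float = 0.1
    t_ratio_penalty: float = 5.0
    distance_space: str = "original"   # or "pc"
    # input paths (None -> simulate)
    compositions_path: str | None = None
    confounds_path: str | None = None
    features_path: str | None = None
    feature_kinds: dict = field(default_factory=dict)
    maps_path: str | None = None
    groups: dict = field(default_factory=dict)   # label -> compositions path
    run_loo: bool = False
    simulate: dict = field(default_factory=dict)  # parameters for synthetic data

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        for name in ("q_enrich", "q_posthoc"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.distance_space not in ("original", "pc"):
            raise ValueError("distance_space must be 'original' or 'pc'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        # analysis-relevant parameters only: where outputs land does not
        # change what is computed
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def validate_tables(
    compositions_path,
    confounds_path=None,
    features_path=None,
) -> list[str]:
    """Schema/consistency report across the input tables (empty = valid)."""
    violations: list[str] = []
    try:
        comp = read_table(compositions_path)
    except Exception as exc:
        return [f"compositions unreadable: {exc}"]
    if comp.isna().any().any():
        violations.append("compositions contain missing values")
    if (comp.to_numpy(dtype=float) < 0).any():
        violations.append("compositions contain negative proportions")
    if not np.allclose(comp.sum(axis=1).to_numpy(), 1.0, atol=1e-6):
        violations.append("composition rows do not sum to 1")
    for name, path in (("confounds", confounds_path), ("features", features_path)):
        if path is None:
            continue
        try:
            tbl = read_table(path)
        except Exception as exc:
            violations.append(f"{name} unreadable: {exc}")
            continue
        if list(tbl.index) != list(comp.index):
            violations.append(f"{name} subject ids misaligned with compositions")
        if name == "confounds" and tbl.isna().any().any():
            violations.append("confounds contain missing values")
    return violations


def _simulate_inputs(cfg: RunConfig, out: Path):
    """Generate compositions, confounds, features and maps with ground truth."""
    sim = dict(cfg.simulate)
    k = sim.get("k", cfg.k)
    d = sim.get("d", 19)
    n = sim.get("n", 900)
    noise_frac = sim.get("noise_frac", 0.02)
    alpha = sim.get("dirichlet_alpha", 1.0)
    seed = substream_seed(cfg.seed, "simulate")
    rng = np.random.default_rng(seed)

    vertices = syn_mod.generate_vertices(
        k, d, min_separation=sim.get("min_separation", 0.3),
        seed=int(rng.integers(2**31)), on_simplex=True)
    diff = vertices[:, None] - vertices[None]
    diameter = float(np.sqrt((diff**2).sum(-1)).max())
    table, truth = syn_mod.sample_population(
        k, d, n, dirichlet_alpha=alpha, noise_sd=noise_frac * diameter,
        seed=int(rng.integers(2**31)), vertices=vertices)

    n_conf = 3
    conf = ConfoundTable(
        subject_ids=list(table.subject_ids),
        confound_ids=["age", "gender", "mFD"],
        values=np.column_stack([
            rng.normal(16, 1.5, n), rng.integers(0, 2, n), rng.gamma(2.0, 0.05, n),
        ]),
    )
    betas = np.zeros((n_conf, d))
    betas[2, 0] = sim.get("confound_beta", 0.3)  # mFD contaminates first component
    contaminated = syn_mod.add_confounds(
        comp_mod.normalize_variance(np.clip(table.values, 1e-9, None)),
        conf, betas, truth)

    feats = {}
    kinds = {}
    X = contaminated.values
    for a in range(k):
        feats[f"feat_max_a{a}"] = syn_mod.plant_feature(
            X, truth, a, "max", effect_size=sim.get("effect_size", 1.0),
            noise_sd=sim.get("feature_noise", 0.3), seed=int(rng.integers(2**31)),
            feature_id=f"feat_max_a{a}")
        kinds[f"feat_max_a{a}"] = "continuous"
    feats["feat_bool_a0"] = syn_mod.plant_feature(
        X, truth, 0, "max", effect_size=3.0, kind="boolean",
        seed=int(rng.integers(2**31)), feature_id="feat_bool_a0")
    kinds["feat_bool_a0"] = "boolean"
    for j in range(sim.get("n_noise_features", 5)):
        feats[f"noise_{j}"] = rng.normal(size=n)
        kinds[f"noise_{j}"] = "continuous"
    features = pd.DataFrame(feats, index=table.subject_ids)
    # sprinkle missingness for the imputation path
    miss = rng.random(features.shape) < sim.get("missing_rate", 0.02)
    features = features.mask(miss)

    maps = syn_mod.generate_component_maps(
        d, grid_shape=tuple(sim.get("grid_shape", (8, 8, 8))),
        smoothness_scale=sim.get("smoothness_scale", 1.5),
        seed=int(rng.integers(2**31)))

    clin, _ = syn_mod.generate_clinical_subgroup(
        truth, target_archetype=0, shift_fraction=sim.get("shift_fraction", 0.5),
        n=sim.get("n_clinical", 120), seed=int(rng.integers(2**31)))

    write_table(contaminated.to_frame(), out / "compositions.tsv")
    write_table(conf.to_frame(), out / "confounds.tsv")
    write_table(features, out / "features.tsv")
    write_table(clin.to_frame(), out / "clinical_compositions.tsv")
    maps.to_nifti(out / "component_maps.nii.gz")
    truth_json = {
        "vertices": truth.vertices.tolist(),
        "noise_sd": truth.noise_sd,
        "planted_effects": truth.planted_effects,
        "confound_betas": betas.tolist(),
        "seed": seed,
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=1))
    return contaminated, conf, features, kinds, maps, {"clinical": clin}, truth


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages in order; returns the run manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
    }

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                if exc[0] is None:
                    manifest["stages"].setdefault(name, {})["seconds"] = round(
                        time.perf_counter() - self.t0, 3)
        return _Timer()

    stamp = {"seed": cfg.seed, "config_hash": cfg.config_hash()}

    # ---- inputs -----------------------------------------------------------
    with stage("inputs"):
        if cfg.compositions_path is None:
            comp, conf, features_raw, kinds, maps, group_tables, truth = \
                _simulate_inputs(cfg, out)
        else:
            violations = validate_tables(cfg.compositions_path,
                                         cfg.confounds_path, cfg.features_path)
            if violations:
                raise ValueError("input validation failed: " + "; ".join(violations))
            comp = CompositionTable.from_frame(read_table(cfg.compositions_path))
            conf = (ConfoundTable.from_frame(read_table(cfg.confounds_path))
                    if cfg.confounds_path else None)
            features_raw = (read_table(cfg.features_path)
                            if cfg.features_path else None)
            kinds = dict(cfg.feature_kinds)
            maps = (ComponentMaps.from_nifti(cfg.maps_path)
                    if cfg.maps_path else None)
            group_tables = {label: CompositionTable.from_frame(read_table(p))
                            for label, p in cfg.groups.items()}
            truth = None
        manifest["stages"]["inputs"] = {"n_subjects": comp.n_subjects,
                                        "n_components": comp.n_components}

    # ---- adjust -----------------------------------------------------------
    with stage("adjust"):
        if conf is not None:
            adjusted = adjust_confounds(comp, conf)
        else:
            adjusted = AdjustedTable(
                subject_ids=list(comp.subject_ids),
                component_ids=list(comp.component_ids),
                values=comp.values.copy(),
                coefficients=None, confound_ids=[],
                column_means=comp.values.mean(axis=0))
        write_table(adjusted.to_frame(), out / "adjusted.tsv")

    # ---- fit --------------------------------------------------------------
    with stage("fit"):
        fit_seed = substream_seed(cfg.seed, "fit")
        pca, scores, sol = fit_archetypes(adjusted.values, cfg.k,
                                          penalty=cfg.penalty, seed=fit_seed)
        tres = t_ratio_test(adjusted.values, cfg.k, n_shuffles=cfg.n_shuffles,
                            seed=substream_seed(cfg.seed, "tratio"),
                            penalty=cfg.t_ratio_penalty)
        boot = bootstrap_archetypes(adjusted.values, cfg.k, n_boot=cfg.n_boot,
                                    seed=substream_seed(cfg.seed, "bootstrap"),
                                    penalty=cfg.penalty, reference=sol, pca=pca)
        solution = {
            **stamp,
            "k": cfg.k,
            "vertices_pc": sol.vertices_pc.tolist(),
            "vertices_full": sol.vertices_full.tolist(),
            "t_ratio": tres.t_obs,
            "p_value": tres.p_value,
            "n_shuffles": tres.n_shuffles,
            "explained_variance": pca.explained_variance.tolist(),
            "pca_mean": pca.mean.tolist(),
            "pca_loadings": pca.loadings.tolist(),
            "bootstrap": {
                "n_boot": boot.n_boot,
                "n_skipped": boot.n_skipped,
                "vertex_means": boot.means.tolist(),
                "vertex_covariances": boot.covariances.tolist(),
            },
            "diagnostics": sol.diagnostics,
        }
        (out / "solution.json").write_text(json.dumps(solution, indent=1))
        manifest["stages"].setdefault("fit", {}).update(
            {"t_ratio": tres.t_obs, "p_value": tres.p_value})

    # ---- distances --------------------------------------------------------
    if cfg.distance_space == "original":
        distances = distances_to_archetypes(adjusted.values, sol.vertices_full)
    else:
        distances = distances_to_archetypes(scores, sol.vertices_pc)

    # ---- enrichment -------------------------------------------------------
    enr = None
    if features_raw is not None:
        with stage("enrich"):
            features, missing = impute_median(features_raw)
            if conf is not None:  # confounds as control features
                for j, cname in enumerate(conf.confound_ids):
                    features[f"confound_{cname}"] = conf.values[:, j]
            enr = enr_mod.enrich_all(features, distances, kinds,
                                     n_bins=cfg.n_bins, q_threshold=cfg.q_enrich)
            enr_out = enr.drop(columns=["bin_profile"]).assign(**stamp)
            enr_out.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            missing.to_csv(out / "missingness.tsv", sep="\t")
            manifest["stages"].setdefault("enrich", {})["n_significant"] = int(enr["significant"].sum())

            if cfg.run_loo:
                _, robust = enr_mod.leave_one_out(
                    adjusted.values, features, cfg.k, kinds,
                    n_bins=cfg.n_bins, q_threshold=cfg.q_enrich,
                    penalty=cfg.penalty, seed=substream_seed(cfg.seed, "loo"),
                    component_ids=list(adjusted.component_ids))
                robust.assign(**stamp).to_csv(out / "loo_robustness.tsv",
                                              sep="\t", index=False)

    # ---- archetype maps ---------------------------------------------------
    if maps is not None and enr is not None:
        with stage("maps"):
            comp_feats = [f for f in adjusted.component_ids
                          if f in set(enr["feature"])]
            arch_maps = []
            for a in range(cfg.k):
                sub = enr[(enr["archetype"] == a) & (enr["direction"] == "max")]
                w = np.array([
                    sub.loc[sub["feature"] == c, "r"].iloc[0] if c in set(sub["feature"])
                    else 0.0
                    for c in adjusted.component_ids])
                if not np.any(w):
                    # fall back to vertex composition profile as weights
                    w = sol.vertices_full[a] - sol.vertices_full.mean(axis=0)
                arch_maps.append(weighted_map(maps, w))
            arch = ComponentMaps(values=np.column_stack(arch_maps),
                                 coords=maps.coords, grid_shape=maps.grid_shape,
                                 component_ids=[f"archetype_{a}" for a in range(cfg.k)])
            arch.to_nifti(out / "archetype_maps.nii.gz")
            manifest["stages"].setdefault("maps", {})["n_maps"] = cfg.k

    # ---- group comparison -------------------------------------------------
    if group_tables:
        with stage("compare"):
            all_dist = [distances]
            labels = ["reference"] * comp.n_subjects
            for label, table in group_tables.items():
                vals = table.values
                if cfg.distance_space == "original":
                    dist_g = distances_to_archetypes(vals, sol.vertices_full)
                else:
                    dist_g = distances_to_archetypes(pca.transform(vals),
                                                     sol.vertices_pc)
                all_dist.append(dist_g)
                labels += [label] * table.n_subjects
            report = grp_mod.compare_groups(np.vstack(all_dist), labels,
                                            q_threshold=cfg.q_posthoc)
            report.kruskal.assign(**stamp).to_csv(out / "group_kruskal.tsv",
                                                  sep="\t", index=False)
            report.posthoc.assign(**stamp).to_csv(out / "group_posthoc.tsv",
                                                  sep="\t", index=False)

    manifest["outputs"] = sorted(p.name for p in out.iterdir())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
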