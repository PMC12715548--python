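"""End-to-end orchestration of the synthetic subtyping experiment.

Stage order mirrors the study workflow: simulate a cohort with known ground
truth, compute MIND and FC matrices, factorize each modality with the LDA
model, then characterize the factors (control correspondence,
structure-function coupling, behavior correlations, receptor regression with
spin-test p-values).  Every output directory carries the exact config, the
derived seeds and a manifest with SHA-256 hashes of all outputs, and reruns
with the same config are byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import fc as fc_mod
from . import io, lda, spin, stats, synthetic
from .matrices import SimilarityMatrix

log = logging.getLogger("factorscape")

DEFAULT_CONFIG: dict = {
    "n_regions": 20,
    "n_subjects": 60,
    "n_hc_subjects": 30,
    "n_factors": 3,
    "synthetic": {
        "edge_density": 0.3,
        "magnitude": 1.0,
        "dirichlet_alpha": 0.5,
        "noise_sd": 0.05,
        "hc_noise_sd": 0.1,
        "receptor_smoothness": 1,
        # the joint receptor regression needs n_regions > n_maps + 1, so the
        # R=20 demo uses a reduced map set; scale both up together
        "n_receptor_maps": 8,
        "behavior_target_r": 0.3,
        "behavior_scales": ["SCQ", "SRS", "RBSR"],
    },
    "mind": {
        "estimator": "gaussian",
        "k": 3,
        "znorm": True,
        "n_feature_subjects": 3,
        "vertices_per_region": 200,
        "n_features": 5,
        "separation": 1.0,
    },
    "fc": {
        "n_timepoints": 300,
        "coupling": 0.15,
    },
    "lda": {
        "scale_mind": 10.0,
        "scale_fc": 60.0,
        "alpha": None,
        "eta": 0.01,
        "n_restarts": 5,
        "max_iter": 200,
        "tol": 1.0e-5,
    },
    "n_perm": 300,
    "seed": 7,
}


def validate_config(config: dict, template: dict | None = None, path: str = "") -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    template = copy.deepcopy(DEFAULT_CONFIG) if template is None else template
    for key, value in config.items():
        if key not in template:
            raise ValueError(f"unknown config key: {path}{key}")
        if isinstance(template[key], dict) and isinstance(value, dict):
            validate_config(value, template[key], path=f"{path}{key}.")
        else:
            template[key] = value
    return template


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return validate_config(user)


def _derived_seeds(seed: int) -> dict:
    """Named integer sub-seeds (< 2^31), all reproducible from the master seed."""
    state = np.random.SeedSequence(seed).generate_state(12) % (2**31)
    names = [
        "sphere", "receptors", "mind_factors", "mind_cohort", "fc_factors",
        "fc_cohort", "timeseries", "behavior", "lda_mind", "lda_fc",
        "spin", "vertex_features",
    ]
    return {n: int(s) for n, s in zip(names, state)}


def _psd_coupling(mixtures: list[np.ndarray], coupling: float) -> float:
    """Largest c <= coupling keeping I + c*M positive definite for every M."""
    c = coupling
    for m in mixtures:
        lo = float(np.linalg.eigvalsh(m)[0])
        if lo < 0:
            c = min(c, 0.9 / abs(lo))
    return c


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: dict, out_dir) -> dict:
    """Run simulate -> mind -> fc -> factorize -> compare -> behavior -> receptors.

    Returns the manifest dictionary (also written to ``manifest.json``).
    Any stage failure raises with the stage name; outputs of completed stages
    are left in place.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _derived_seeds(cfg["seed"])
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    stages = []
    state: dict = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn(cfg, out, seeds, state)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage=%s wall_s=%.2f", name, time.perf_counter() - t0)
        stages.append(name)

    run_stage("simulate", _stage_simulate)
    run_stage("mind", _stage_mind)
    run_stage("fc", _stage_fc)
    run_stage("factorize", _stage_factorize)
    run_stage("compare", _stage_compare)
    run_stage("behavior", _stage_behavior)
    run_stage("receptors", _stage_receptors)

    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "stages": stages,
        "seed": cfg["seed"],
        "derived_seeds": seeds,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _labels(r: int) -> list[str]:
    return [f"region_{i:03d}" for i in range(r)]


def _stage_simulate(cfg, out, seeds, state) -> None:
    syn = cfg["synthetic"]
    r, n, k = cfg["n_regions"], cfg["n_subjects"], cfg["n_factors"]
    sim = out / "simulate"
    sim.mkdir(exist_ok=True)

    sphere = synthetic.gen_sphere_parcellation(r, seed=seeds["sphere"])
    atlas = synthetic.gen_receptor_maps(
        sphere, n_maps=syn["n_receptor_maps"],
        smoothness=syn["receptor_smoothness"], seed=seeds["receptors"],
    )
    io.write_receptor_atlas(atlas, sim / "receptors.tsv", sim / "sphere.tsv")

    # MIND-side ground truth and mixture cohort (stands for z-normed MIND)
    f_mind = synthetic.gen_factor_truth(
        k, r, edge_density=syn["edge_density"], magnitude=syn["magnitude"],
        seed=seeds["mind_factors"],
    )
    mats_mind, load_mind = synthetic.gen_cohort_matrices(
        f_mind, n, dirichlet_alpha=syn["dirichlet_alpha"],
        noise_sd=syn["noise_sd"], seed=seeds["mind_cohort"],
    )
    mind_dir = sim / "mind_cohort"
    mind_dir.mkdir(exist_ok=True)
    for i, m in enumerate(mats_mind):
        io.write_matrix(
            SimilarityMatrix(m, "signed", _labels(r)),
            mind_dir / f"sub_{i:04d}.tsv",
            sidecar={"subject": f"sub_{i:04d}", "modality": "mind"},
        )

    # FC-side ground truth: mixtures become population correlation targets
    f_fc = synthetic.gen_factor_truth(
        k, r, edge_density=syn["edge_density"], magnitude=syn["magnitude"],
        seed=seeds["fc_factors"],
    )
    _, load_fc = synthetic.gen_cohort_matrices(
        f_fc, n, dirichlet_alpha=syn["dirichlet_alpha"],
        noise_sd=0.0, seed=seeds["fc_cohort"],
    )
    mixtures = [np.tensordot(load_fc[i], np.stack(f_fc), axes=1) for i in range(n)]
    c = _psd_coupling(mixtures, cfg["fc"]["coupling"])
    ts_dir = sim / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    ts_seeds = np.random.SeedSequence(seeds["timeseries"]).generate_state(n) % (2**31)
    for i, m in enumerate(mixtures):
        target = np.eye(r) + c * m
        ts = synthetic.gen_timeseries(r, cfg["fc"]["n_timepoints"], target, seed=int(ts_seeds[i]))
        io.write_timeseries(ts, _labels(r), ts_dir / f"sub_{i:04d}.tsv")

    # healthy-control cohorts: one fixed pattern per modality plus subject noise
    hc_weights = np.array([0.5, 0.3, 0.2][:k])
    hc_weights = hc_weights / hc_weights.sum()
    hc_mind_pattern = np.tensordot(hc_weights, np.stack(f_mind), axes=1)
    hc_mats, _ = synthetic.gen_cohort_matrices(
        [hc_mind_pattern], cfg["n_hc_subjects"], dirichlet_alpha=1.0,
        noise_sd=syn["hc_noise_sd"], seed=seeds["mind_cohort"] + 1,
    )
    hc_mind = fc_mod.group_average(
        [SimilarityMatrix(m, "signed", _labels(r)) for m in hc_mats]
    )
    io.write_matrix(hc_mind, sim / "hc_average_mind.tsv")
    hc_fc_pattern = np.tensordot(hc_weights, np.stack(f_fc), axes=1)
    hc_fc_seeds = np.random.SeedSequence(seeds["timeseries"] + 1).generate_state(
        cfg["n_hc_subjects"]
    ) % (2**31)
    hc_fc_mats = []
    for i in range(cfg["n_hc_subjects"]):
        target = np.eye(r) + _psd_coupling([hc_fc_pattern], cfg["fc"]["coupling"]) * hc_fc_pattern
        ts = synthetic.gen_timeseries(r, cfg["fc"]["n_timepoints"], target, seed=int(hc_fc_seeds[i]))
        hc_fc_mats.append(fc_mod.fc_from_timeseries(ts, _labels(r)))
    io.write_matrix(fc_mod.group_average(hc_fc_mats), sim / "hc_average_fc.tsv")

    # behavior coupled to MIND-side loadings only (RBSR row is a true null)
    scales = syn["behavior_scales"]
    effects = np.zeros((len(scales), k))
    effects[0, min(1, k - 1)] = 1.0   # SCQ <- factor 2
    effects[1, 0] = -1.0              # SRS <- factor 1 (negative)
    noise_sd = synthetic.behavior_noise_for_target_r(
        synthetic.dirichlet_loading_variance(syn["dirichlet_alpha"], k),
        1.0, syn["behavior_target_r"],
    )
    behavior = synthetic.gen_behavior(
        load_mind, effects, noise_sd=noise_sd, seed=seeds["behavior"], scale_names=scales
    )
    behavior.insert(0, "subject", [f"sub_{i:04d}" for i in range(n)])
    io.write_table(behavior, sim / "behavior.tsv")

    # vertex-feature tables for the MIND estimation stage
    vf_dir = sim / "vertex_features"
    vf_dir.mkdir(exist_ok=True)
    vf_seeds = np.random.SeedSequence(seeds["vertex_features"]).generate_state(
        cfg["mind"]["n_feature_subjects"]
    ) % (2**31)
    true_kl = None
    for i in range(cfg["mind"]["n_feature_subjects"]):
        table, kl = synthetic.gen_vertex_features(
            r, vertices_per_region=cfg["mind"]["vertices_per_region"],
            n_features=cfg["mind"]["n_features"],
            separation=cfg["mind"]["separation"],
            seed=int(vf_seeds[i]), region_labels=_labels(r),
        )
        io.write_vertex_features(table, vf_dir / f"sub_{i:04d}.tsv")
        if true_kl is None:
            true_kl = kl
        io.write_matrix(
            SimilarityMatrix(1.0 / (1.0 + kl), "mind_raw", _labels(r)),
            vf_dir / f"sub_{i:04d}_truth.tsv",
            sidecar={"content": "truth-derived MIND from closed-form KL"},
        )

    # ground-truth bundle
    truth_dir = sim / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name, mats in (("mind", f_mind), ("fc", f_fc)):
        for j, m in enumerate(mats):
            io.write_matrix(
                SimilarityMatrix(m, "signed", _labels(r)),
                truth_dir / f"factor_{name}_{j + 1}.tsv",
            )
    io.write_loadings(load_mind, truth_dir / "loadings_mind.tsv")
    io.write_loadings(load_fc, truth_dir / "loadings_fc.tsv")
    eff = [{"scale": s, **{f"factor_{j + 1}": float(effects[i, j]) for j in range(k)}}
           for i, s in enumerate(scales)]
    (truth_dir / "ground_truth.json").write_text(json.dumps(
        {
            "behavior_effects": eff,
            "behavior_noise_sd": float(noise_sd),
            "fc_coupling": float(c),
            "hc_weights": hc_weights.tolist(),
        },
        indent=2, sort_keys=True,
    ) + "\n")

    state.update(
        sphere=sphere, atlas=atlas, f_mind=f_mind, f_fc=f_fc,
        mats_mind=mats_mind, load_mind=load_mind, load_fc=load_fc,
        fc_coupling=c, behavior=behavior, hc_mind=hc_mind,
    )


def _stage_mind(cfg, out, seeds, state) -> None:
    from .mind import mind_matrix

    mdir = out / "mind"
    mdir.mkdir(exist_ok=True)
    vf_dir = out / "simulate" / "vertex_features"
    for path in sorted(vf_dir.glob("sub_*.tsv")):
        if path.stem.endswith("_truth"):
            continue
        table = io.read_vertex_features(path)
        sm = mind_matrix(
            table, estimator=cfg["mind"]["estimator"], k=cfg["mind"]["k"],
            znorm=cfg["mind"]["znorm"],
        )
        io.write_matrix(
            sm, mdir / f"{path.stem}_mind.tsv",
            sidecar={
                "estimator": cfg["mind"]["estimator"], "k": cfg["mind"]["k"],
                "znorm": cfg["mind"]["znorm"], "subject": path.stem,
            },
        )


def _stage_fc(cfg, out, seeds, state) -> None:
    fdir = out / "fc"
    fdir.mkdir(exist_ok=True)
    ts_dir = out / "simulate" / "timeseries"
    mats = []
    for path in sorted(ts_dir.glob("sub_*.tsv")):
        ts, labels = io.read_timeseries(path)
        sm = fc_mod.fc_from_timeseries(ts, labels)
        io.write_matrix(sm, fdir / f"{path.stem}_fc.tsv", sidecar={"subject": path.stem})
        mats.append(sm)
    state["mats_fc"] = mats


def _stage_factorize(cfg, out, seeds, state) -> None:
    k = cfg["n_factors"]
    ldacfg = cfg["lda"]
    for modality, mats, scale, lseed in (
        ("mind", state["mats_mind"], ldacfg["scale_mind"], seeds["lda_mind"]),
        ("fc", [m.values * 1.0 for m in state["mats_fc"]], ldacfg["scale_fc"], seeds["lda_fc"]),
    ):
        arrs = []
        for m in mats:
            arr = np.array(m, dtype=float)
            np.fill_diagonal(arr, 0.0)
            arrs.append(arr)
        docs = lda.documents_from_matrices(arrs, scale=scale)
        fs, loadings = lda.fit_lda(
            docs, k, alpha=ldacfg["alpha"], eta=ldacfg["eta"],
            n_restarts=ldacfg["n_restarts"], max_iter=ldacfg["max_iter"],
            tol=ldacfg["tol"], seed=lseed, n_regions=cfg["n_regions"],
        )
        # align to generator truth so factor numbering is stable across seeds
        perm, match = lda.align_matrices(state[f"f_{modality}"], fs.signed_matrices)
        fs = fs.permuted(perm)
        loadings = loadings[:, perm]
        fdir = out / "factors" / modality
        fdir.mkdir(parents=True, exist_ok=True)
        for j, m in enumerate(fs.signed_matrices):
            io.write_matrix(
                SimilarityMatrix(m, "signed", _labels(cfg["n_regions"])),
                fdir / f"factor_{j + 1}.tsv",
                sidecar={"modality": modality, "factor": j + 1},
            )
        io.write_loadings(loadings, fdir / "loadings.tsv")
        meta = dict(fs.meta)
        meta["truth_alignment_r"] = [float(x) for x in match]
        meta["scale"] = scale
        (fdir / "fit_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
        state[f"factors_{modality}"] = fs
        state[f"loadings_{modality}"] = loadings


def _stage_compare(cfg, out, seeds, state) -> None:
    cdir = out / "compare"
    cdir.mkdir(exist_ok=True)
    k = cfg["n_factors"]
    hc_mind = io.read_matrix(out / "simulate" / "hc_average_mind.tsv")
    hc_fc = io.read_matrix(out / "simulate" / "hc_average_fc.tsv")
    for modality, hc in (("mind", hc_mind), ("fc", hc_fc)):
        tbl = stats.factor_correspondence(
            state[f"factors_{modality}"].signed_matrices, [hc],
            names_a=[f"{modality.upper()}F{j + 1}" for j in range(k)],
            names_b=[f"HC_{modality}"],
        )
        io.write_table(tbl, cdir / f"hc_correspondence_{modality}.tsv")
    coupling = stats.factor_correspondence(
        state["factors_mind"].signed_matrices,
        state["factors_fc"].signed_matrices,
        names_a=[f"MINDF{j + 1}" for j in range(k)],
        names_b=[f"FCF{j + 1}" for j in range(k)],
    )
    io.write_table(coupling, cdir / "structure_function_coupling.tsv")


def _stage_behavior(cfg, out, seeds, state) -> None:
    bdir = out / "behavior"
    bdir.mkdir(exist_ok=True)
    behavior = io.read_table(out / "simulate" / "behavior.tsv").drop(columns=["subject"])
    k = cfg["n_factors"]
    for modality in ("mind", "fc"):
        tbl = stats.loading_behavior_correlations(
            state[f"loadings_{modality}"], behavior,
            factor_names=[f"{modality.upper()}F{j + 1}" for j in range(k)],
        )
        io.write_table(tbl, bdir / f"loading_behavior_{modality}.tsv")


def _stage_receptors(cfg, out, seeds, state) -> None:
    rdir = out / "receptors"
    rdir.mkdir(exist_ok=True)
    atlas = io.read_receptor_atlas(
        out / "simulate" / "receptors.tsv", out / "simulate" / "sphere.tsv"
    )
    null = spin.build_spin_null(atlas.sphere, n_perm=cfg["n_perm"], seed=seeds["spin"])
    frames = []
    for modality in ("mind", "fc"):
        for j, m in enumerate(state[f"factors_{modality}"].signed_matrices):
            pc = stats.pca_first_component(m)
            tbl = spin.spin_pvalues(pc, atlas, null)
            tbl.insert(0, "factor", f"{modality.upper()}F{j + 1}")
            frames.append(tbl)
    import pandas as pd

    io.write_table(pd.concat(frames, ignore_index=True), rdir / "receptor_regression.tsv")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_inputs(out_dir) -> dict:
    """Consistency report over a pipeline output directory.

    Checks matrix symmetry, region-label agreement across files and the
    simplex constraint on loadings; returns ``{"violations": [...]}`` (empty
    list means a consistent bundle).
    """
    out = Path(out_dir)
    violations: list[str] = []
    labels_seen: dict[int, list[str]] = {}
    for path in sorted(out.rglob("*.tsv")):
        name = str(path.relative_to(out))
        if "loadings" in path.name:
            try:
                loadings, _ = io.read_loadings(path)
            except Exception as exc:  # unreadable file is itself a violation
                violations.append(f"{name}: unreadable ({exc})")
                continue
            if np.any(loadings < -1e-12):
                violations.append(f"{name}: negative loading values")
            bad = np.abs(loadings.sum(axis=1) - 1.0) > 1e-6
            if np.any(bad):
                violations.append(
                    f"{name}: {int(bad.sum())} loading rows do not sum to 1"
                )
            continue
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            continue  # not a matrix file
        try:
            import pandas as pd

            df = pd.read_csv(path, sep="\t")
            values = df.to_numpy(dtype=float)
        except Exception as exc:
            violations.append(f"{name}: unreadable matrix ({exc})")
            continue
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            violations.append(f"{name}: non-square matrix {values.shape}")
            continue
        if not np.allclose(values, values.T, atol=1e-8):
            violations.append(f"{name}: asymmetric matrix")
        labels = list(df.columns)
        key = values.shape[0]
        if key in labels_seen and labels_seen[key] != labels:
            violations.append(f"{name}: region labels disagree with other files")
        labels_seen.setdefault(key, labels)
    return {"violations": violations}
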