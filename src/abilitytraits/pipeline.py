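"""End-to-end orchestration of the ability-trait analysis chain.

Stages: synthesize (or load) cohorts -> filter/impute/scale -> factor
model on the reference cohort, frozen and transferred -> cluster fit and
cross-cohort assignment -> L1 ensemble on brain features -> network
annotation of the stable features -> twin heritability and kinship
distance profiles. Each stage reads its inputs from, and writes its
artifacts to, the output directory, so any stage can be rerun in
isolation; a manifest records seeds, row counts and artifact checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import brainreg, clusters, factors, io, netannot, preprocess, synthgen, twinherit
from .datatypes import ScalingParams, ScoreMatrix

__all__ = ["PipelineConfig", "run_full_pipeline", "STAGES"]

STAGES = (
    "synth",
    "preprocess",
    "factors",
    "clusters",
    "brainreg",
    "annotate",
    "heritability",
)


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # synthesis
    n_reference: int = 1369
    generator_overrides: dict = field(default_factory=dict)
    ace_overrides: dict = field(default_factory=dict)
    brain_overrides: dict = field(default_factory=dict)
    # factors / clusters
    k_factors: int | None = None  # None -> parallel analysis decides
    k_range: tuple[int, ...] = tuple(range(1, 9))
    n_stability_subsets: int = 10
    # brain regression
    ensemble_runs: int = 100
    candidate_runs: int = 3
    regression_overrides: dict = field(default_factory=dict)
    # heritability
    n_boot: int = 200
    n_unrelated_pairs: int = 200

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        return cls(**d)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_scores(outdir: Path, stem: str) -> ScoreMatrix:
    return ScoreMatrix.from_csv(outdir / f"{stem}.csv", outdir / "variable_meta.csv")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_synth(cfg: PipelineConfig, outdir: Path) -> dict:
    gcfg = synthgen.default_generator_config(
        n_subjects=cfg.n_reference, seed=cfg.seed, **cfg.generator_overrides
    )
    acfg = synthgen.default_ace_config(seed=cfg.seed + 1, **cfg.ace_overrides)
    bcfg = synthgen.default_brain_config(seed=cfg.seed + 2, **cfg.brain_overrides)

    ref_scores, ref_demo, ref_traits, ref_labels = synthgen.generate_toolbox_cohort(gcfg)
    ref_scores = synthgen.inject_missingness(ref_scores, gcfg.missing_rate, seed=cfg.seed + 3)

    fam_scores, kinship, truth = synthgen.generate_family_cohort(gcfg, acfg)
    fam_scores = synthgen.inject_missingness(fam_scores, gcfg.missing_rate, seed=cfg.seed + 4)
    rng = np.random.default_rng(cfg.seed + 5)
    fam_demo = pd.DataFrame(
        {
            "age": rng.uniform(22, 35, size=fam_scores.n_subjects),
            "gender": truth["gender"].to_numpy(),
        },
        index=fam_scores.values.index,
    )
    brain = synthgen.generate_brain_features(truth["traits"], bcfg)

    ref_scores.to_csv(outdir / "reference_scores.csv", outdir / "variable_meta.csv")
    fam_scores.to_csv(outdir / "transfer_scores.csv")
    ref_demo.to_csv(outdir / "reference_demo.csv", index_label="subject")
    fam_demo.to_csv(outdir / "transfer_demo.csv", index_label="subject")
    io.write_kinship(kinship, outdir / "kinship.csv")
    io.write_netmats(brain, outdir / "netmats.txt")
    brain.of_kind("morphology").to_csv(outdir / "morphology.csv", index_label="subject")
    truth_payload = {
        "reference_labels": ref_labels.tolist(),
        "components": truth["components"],
        "true_support": bcfg.true_support,
        "n_ics": bcfg.n_ics,
    }
    (outdir / "truth.json").write_text(json.dumps(truth_payload, indent=1))
    ref_traits.to_csv(outdir / "reference_traits_true.csv", index_label="subject")
    truth["traits"].to_csv(outdir / "transfer_traits_true.csv", index_label="subject")
    return {
        "n_reference": ref_scores.n_subjects,
        "n_transfer": fam_scores.n_subjects,
        "n_kinship_pairs": len(kinship),
    }


def stage_preprocess(cfg: PipelineConfig, outdir: Path) -> dict:
    counts = {}
    ref = _load_scores(outdir, "reference_scores")
    demo = pd.read_csv(outdir / "reference_demo.csv", index_col="subject")
    ref, report = preprocess.filter_subjects(ref, demo)
    preprocess.write_exclusion_report(report, outdir / "reference_exclusions.tsv")
    ref = preprocess.impute_mean(ref)
    params = preprocess.fit_reference_scaling(ref)
    params.to_json(outdir / "scaling.json")
    ref_scaled = preprocess.apply_scaling(ref, params)
    ref_scaled.to_csv(outdir / "reference_scaled.csv")
    counts["n_reference_kept"] = report["n_kept"]

    tra = _load_scores(outdir, "transfer_scores")
    demo_t = pd.read_csv(outdir / "transfer_demo.csv", index_col="subject")
    tra, report_t = preprocess.filter_subjects(tra, demo_t)
    preprocess.write_exclusion_report(report_t, outdir / "transfer_exclusions.tsv")
    tra = preprocess.impute_mean(tra)
    tra_scaled = preprocess.apply_scaling(tra, params)  # reference scale, by design
    tra_scaled.to_csv(outdir / "transfer_scaled.csv")
    counts["n_transfer_kept"] = report_t["n_kept"]
    return counts


def stage_factors(cfg: PipelineConfig, outdir: Path) -> dict:
    ref = _load_scores(outdir, "reference_scaled")
    k = cfg.k_factors or factors.parallel_analysis(ref, seed=cfg.seed + 10)
    fm = factors.varimax_rotate(factors.fit_factor_model(ref, k))
    fm.to_json(outdir / "factor_model.json")
    for stem in ("reference", "transfer"):
        m = _load_scores(outdir, f"{stem}_scaled")
        scores = factors.score_subjects(fm, m)
        scores.to_csv(outdir / f"{stem}_trait_scores.csv", index_label="subject")
    return {
        "k_factors": k,
        "variance_explained": factors.variance_explained(fm),
    }


def stage_clusters(cfg: PipelineConfig, outdir: Path) -> dict:
    ref = pd.read_csv(outdir / "reference_trait_scores.csv", index_col="subject")
    K_best, bic, ari = clusters.select_k(
        ref, k_range=cfg.k_range, n_subsets=cfg.n_stability_subsets, seed=cfg.seed + 20
    )
    pd.DataFrame({"bic": bic, "ari_stability": ari}).to_csv(
        outdir / "cluster_selection.tsv", sep="\t", index_label="K"
    )
    cm = clusters.fit_gmm(ref, K_best, seed=cfg.seed + 21)
    cm.to_json(outdir / "cluster_model.json")
    hash_before = cm.model_hash()
    out = {"K_best": K_best, "model_hash": hash_before}
    for stem in ("reference", "transfer"):
        t = pd.read_csv(outdir / f"{stem}_trait_scores.csv", index_col="subject")
        labels, _ = clusters.assign_clusters(cm, t)
        pd.Series(labels, index=t.index, name="cluster").to_csv(
            outdir / f"{stem}_clusters.csv"
        )
        demo = pd.read_csv(outdir / f"{stem}_demo.csv", index_col="subject")
        demo = demo.loc[t.index]
        profile, tests = clusters.cluster_covariate_profile(labels, demo)
        profile.to_csv(outdir / f"{stem}_cluster_profile.tsv", sep="\t")
        tests.to_csv(outdir / f"{stem}_cluster_outlier_tests.tsv", sep="\t", index=False)
        out[f"n_{stem}_clustered"] = len(labels)
    assert cm.model_hash() == hash_before, "transfer must not alter the model"
    return out


def _load_brain(outdir: Path, cfg: PipelineConfig) -> brainreg.BrainFeatureSet:
    traits = pd.read_csv(outdir / "transfer_trait_scores.csv", index_col="subject")
    fs = io.read_netmats(outdir / "netmats.txt", subjects=list(traits.index))
    morph = pd.read_csv(outdir / "morphology.csv", index_col="subject")
    feats = pd.concat([fs.features, morph], axis=1)
    meta = pd.concat(
        [
            fs.feature_meta,
            pd.DataFrame(
                {"kind": ["morphology"] * morph.shape[1], "ic_pair": [""] * morph.shape[1]},
                index=pd.Index(morph.columns, name="feature"),
            ),
        ]
    )
    full = brainreg.BrainFeatureSet(feats, meta, fs.provenance)
    demo = pd.read_csv(outdir / "transfer_demo.csv", index_col="subject")
    return brainreg.attach_demographics(full, demo.loc[traits.index])


def stage_brainreg(cfg: PipelineConfig, outdir: Path) -> dict:
    traits = pd.read_csv(outdir / "transfer_trait_scores.csv", index_col="subject")
    rcfg = brainreg.RegressionConfig(seed=cfg.seed + 30, **cfg.regression_overrides)
    full = _load_brain(outdir, cfg)

    # candidate comparison: with vs without demographics on the same features
    rows = []
    for name, use_demo in [("with_demographics", True), ("without_demographics", False)]:
        cand_cfg = replace(rcfg, include_demographics=use_demo)
        ens = brainreg.run_ensemble(
            full, traits, cand_cfg, n_runs=cfg.candidate_runs,
            alpha_override=rcfg.lambda_optimal,
        )
        rows.append({"candidate": name, "mean_oos_r2": float(ens.oos_r2_mean.mean())})
    scoreboard = pd.DataFrame(rows).set_index("candidate")
    scoreboard.to_csv(outdir / "candidate_scoreboard.tsv", sep="\t")

    ens_opt = brainreg.run_ensemble(
        full, traits, rcfg, n_runs=cfg.ensemble_runs, alpha_override=rcfg.lambda_optimal
    )
    ens_opt.to_json(outdir / "ensemble_optimal.json")
    ens_int = brainreg.run_ensemble(
        full, traits, rcfg, n_runs=cfg.ensemble_runs, alpha_override=rcfg.lambda_interpret
    )
    ens_int.to_json(outdir / "ensemble_interpret.json")
    stable = brainreg.prevalent_features(
        ens_int, feature_meta=full.feature_meta, threshold=rcfg.prevalence_threshold
    )
    stable_rows = []
    for trait, tab in stable.items():
        for feat, row in tab.iterrows():
            stable_rows.append(
                {"trait": trait, "feature": feat,
                 "prevalence": row["prevalence"],
                 "mean_coefficient": row["mean_coefficient"]}
            )
    pd.DataFrame(
        stable_rows, columns=["trait", "feature", "prevalence", "mean_coefficient"]
    ).to_csv(outdir / "stable_features.tsv", sep="\t", index=False)
    return {
        "mean_oos_r2_optimal": float(ens_opt.oos_r2_mean.mean()),
        "mean_oos_r2_interpret": float(ens_int.oos_r2_mean.mean()),
        "n_stable_features": len(stable_rows),
    }


def stage_annotate(cfg: PipelineConfig, outdir: Path) -> dict:
    truth = json.loads((outdir / "truth.json").read_text())
    n_ics = int(truth.get("n_ics", 50))
    maps, templates, _ = synthgen.generate_ic_maps_and_templates(
        n_ics=n_ics, n_templates=8, n_voxels=2000, seed=cfg.seed + 40
    )
    template_labels = [
        "executive_control", "default_mode", "salience", "precuneus",
        "sensorimotor", "language", "auditory", "visual",
    ]
    table = netannot.match_templates(maps, templates, template_labels)
    table.to_csv(outdir / "ic_network_labels.tsv", sep="\t")

    stable = pd.read_csv(outdir / "stable_features.tsv", sep="\t")
    labels = table["label"]
    annotated = []
    for _, row in stable.iterrows():
        feat = row["feature"]
        if feat.startswith("conn_"):
            _, i, j = feat.split("_")
            row = dict(row)
            row["network_pair"] = f"{labels.get(int(i))}-{labels.get(int(j))}"
        else:
            row = dict(row)
            row["network_pair"] = ""
        annotated.append(row)
    pd.DataFrame(annotated).to_csv(outdir / "stable_features_annotated.tsv",
                                   sep="\t", index=False)
    return {"n_ics_annotated": len(table)}


def stage_heritability(cfg: PipelineConfig, outdir: Path) -> dict:
    traits = pd.read_csv(outdir / "transfer_trait_scores.csv", index_col="subject")
    demo = pd.read_csv(outdir / "transfer_demo.csv", index_col="subject").loc[traits.index]
    kinship = io.read_kinship(outdir / "kinship.csv")
    kinship = kinship[
        kinship["subject_a"].isin(traits.index) & kinship["subject_b"].isin(traits.index)
    ]
    pairs = twinherit.enumerate_pairs(
        kinship, traits.index, n_unrelated=cfg.n_unrelated_pairs, seed=cfg.seed + 50
    )
    dist = twinherit.kinship_distance_profile(traits, pairs)
    dist.to_csv(outdir / "kinship_distances_traits.tsv", sep="\t")

    stable = pd.read_csv(outdir / "stable_features.tsv", sep="\t")
    feats = sorted(set(stable["feature"]))
    if feats:
        brain = _load_brain(outdir, cfg)
        cols = [f for f in feats if f in brain.features.columns]
        if cols:
            twinherit.kinship_distance_profile(brain.features[cols], pairs).to_csv(
                outdir / "kinship_distances_brain.tsv", sep="\t"
            )

    estimates = {}
    for trait in traits.columns:
        corrected = twinherit.gender_correct(traits[trait], demo["gender"])
        estimates[trait] = twinherit.falconer_ace(
            corrected, pairs["MZ"], pairs["DZ"], n_boot=cfg.n_boot, seed=cfg.seed + 51
        )
    table = twinherit.ace_table(estimates)
    table.to_csv(outdir / "ace_table.tsv", sep="\t")
    return {"n_traits_tested": len(estimates),
            "n_significant": int((table["status"] == "ok").sum())}


_STAGE_FUNCS = {
    "synth": stage_synth,
    "preprocess": stage_preprocess,
    "factors": stage_factors,
    "clusters": stage_clusters,
    "brainreg": stage_brainreg,
    "annotate": stage_annotate,
    "heritability": stage_heritability,
}


def run_full_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run the configured stages in order; return and write the manifest."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "config": _jsonable(asdict(cfg)), "stages": {}}
    for stage in STAGES:
        if stage not in cfg.stages:
            if stage == "brainreg" and "annotate" in cfg.stages:
                print("warning: annotate skipped because brainreg is disabled")
            continue
        if stage == "annotate" and "brainreg" not in cfg.stages:
            continue
        try:
            manifest["stages"][stage] = _STAGE_FUNCS[stage](cfg, outdir)
        except Exception as exc:
            manifest["stages"][stage] = {"error": str(exc)}
            (outdir / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=1))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    manifest["artifacts"] = {
        p.name: _checksum(p)
        for p in sorted(outdir.glob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return {"columns": list(obj.columns), "values": obj.to_numpy().tolist()}
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
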