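"""End-to-end pipeline: simulate -> qc -> gwas -> discover -> prs -> report.

One YAML/dict config drives every stage; a single global seed fans out into
per-stage child seeds by stable derivation, so an individual stage is
reproducible under partial reruns. Every run writes a machine-readable
manifest (config hash, seed, stage timings, output paths and hashes); a
stage whose outputs already exist with a matching config hash is resumed
from disk instead of recomputed. Stage outputs are plain TSV/JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import discover, gwas, prs, qc, synthgen
from .containers import GenotypeMatrix

log = logging.getLogger(__name__)

__version__ = "0.1.0"

STAGES = ("simulate", "qc", "gwas", "discover", "prs", "report")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_per_stratum": {"EA": 600, "AA": 600},
        "population": {
            "n_variants": 400,
            "n_blocks": 80,
            "block_size": 5,
            "within_block_r2": 0.3,
            "fst_divergence": 0.05,
        },
        "traits": [
            {"name": "hdl", "kind": "quantitative", "n_causal": 40,
             "h2": 0.3, "ancestry_effect_corr": 0.7},
            {"name": "t2d", "kind": "binary", "n_causal": 40, "h2": 0.3,
             "prevalence": 0.169, "ancestry_effect_corr": 0.7},
        ],
        "reference_n": 100000,
        "reference_trait": "hdl",
    },
    "qc": {
        "call_rate_min": 0.95,
        "maf_min": 0.01,
        "hwe_p_min": 1e-5,
        "sample_call_rate_min": 0.90,
        "pihat_max": 0.9,
    },
    "gwas": {
        "trait": "hdl",
        "model": "linear",
        "covariates": ["sex", "age", "site", "art"],
        "n_pcs": 4,
    },
    "discover": {"p_cohort": 0.01, "p_reference": 0.05, "ci_level": 0.99},
    "prs": {
        "trait": "hdl",
        "thresholds": [1e-1, 1e-2, 1e-3, 1e-4],
        "crossval_threshold": 1e-2,
        "k_folds": 10,
        "n_pcs": 4,
        "disease": "t2d",
        "top_fractions": [0.05, 0.10, 0.15, 0.20, 0.25, 0.30],
    },
    "report": {},
}


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int
    version: str = __version__
    stage_seconds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # stage -> {name: path}
    output_hashes: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def validate_config(config: dict) -> dict:
    """Merge over defaults and reject unknown keys (listed in the error)."""
    bad = [k for k in config if k not in DEFAULT_CONFIG and k != "outdir"]
    for stage, sub in config.items():
        if stage in DEFAULT_CONFIG and isinstance(sub, dict):
            bad += [f"{stage}.{k}" for k in sub
                    if k not in DEFAULT_CONFIG[stage]]
    if bad:
        raise ValueError(f"unknown config keys: {bad}")
    merged = {k: (v.copy() if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    for k, v in config.items():
        if isinstance(v, dict) and k in merged:
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed derived from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def run_pipeline(config: dict, outdir) -> RunManifest:
    """Execute the requested stages in dependency order; see module docs."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(config_hash=_hash_obj(cfg), seed=seed)

    state: dict = {}
    for stage in STAGES:
        marker = outdir / f"{stage}.stage.json"
        stage_cfg_hash = _hash_obj({**cfg.get(stage, {}), "seed": seed})
        t0 = time.time()
        resumed = False
        if marker.exists():
            try:
                prev = json.loads(marker.read_text())
                if prev.get("config_hash") == stage_cfg_hash:
                    _load_stage(stage, outdir, state)
                    resumed = True
                    log.info("stage %s resumed from existing outputs", stage)
            except Exception:  # stale marker: recompute
                resumed = False
        if not resumed:
            _run_stage(stage, cfg, seed, outdir, state)
            marker.write_text(json.dumps({"config_hash": stage_cfg_hash}))
            # re-hydrate from the just-written files so downstream stages see
            # the same (text-canonicalised) values on fresh and resumed runs
            try:
                _load_stage(stage, outdir, state)
            except RuntimeError:
                pass
        manifest.stage_seconds[stage] = round(time.time() - t0, 3)
        manifest.outputs[stage] = {
            p.name: str(p) for p in sorted(outdir.glob(f"{stage}.*"))
            if not p.name.endswith(".stage.json")
        }
        manifest.output_hashes[stage] = {
            name: _hash_file(Path(path))
            for name, path in manifest.outputs[stage].items()
        }
    manifest.to_json(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _run_stage(stage: str, cfg: dict, seed: int, outdir: Path, state: dict):
    if stage == "simulate":
        sc = cfg["simulate"]
        pop = synthgen.PopulationSpec(**sc["population"])
        traits = [synthgen.TraitSpec(**t) for t in sc["traits"]]
        cohort = synthgen.simulate_cohort(
            pop, traits, sc["n_per_stratum"], stage_seed(seed, "simulate")
        )
        ref_trait = sc["reference_trait"]
        effects = (
            cohort.truth[cohort.truth["trait"] == ref_trait]
            .rename(columns={"beta_EA": "beta"})[["variant_id", "beta"]]
        )
        h2 = next(t.h2 for t in traits if t.name == ref_trait)
        ref = synthgen.simulate_reference_sumstats(
            cohort.genotypes, effects, h2, sc["reference_n"],
            stage_seed(seed, "reference"), stratum="EA",
        )
        state.update(genotypes=cohort.genotypes, cohort=cohort.cohort,
                     truth=cohort.truth, reference=ref, traits=traits)
        cohort.genotypes.to_tsv(outdir / "simulate.dosages.tsv")
        cohort.cohort.to_csv(outdir / "simulate.cohort.tsv", sep="\t", index=False)
        cohort.truth.to_csv(outdir / "simulate.truth.tsv", sep="\t", index=False)
        ref.to_csv(outdir / "simulate.reference.tsv", sep="\t", index=False)
        (outdir / "simulate.params.yaml").write_text(yaml.safe_dump(sc))

    elif stage == "qc":
        qcfg = cfg["qc"]
        geno, vrep = qc.filter_variants(
            state["genotypes"], qcfg["call_rate_min"], qcfg["maf_min"],
            qcfg["hwe_p_min"],
        )
        geno, srep = qc.filter_samples(
            geno, call_rate_min=qcfg["sample_call_rate_min"],
            pihat_max=qcfg["pihat_max"],
        )
        state["genotypes"] = geno
        state["cohort"] = state["cohort"][
            state["cohort"]["sample_id"].isin(geno.samples)
        ].reset_index(drop=True)
        report = {"variants": vrep.__dict__, "samples": srep.__dict__}
        (outdir / "qc.report.json").write_text(json.dumps(report, indent=2))
        geno.to_tsv(outdir / "qc.dosages.tsv")
        pcs_frames = []
        for s in geno.strata.unique():
            sub = geno.stratum_samples(s)
            k = min(cfg["gwas"]["n_pcs"], sub.n_samples - 2, sub.n_variants - 1)
            if k > 0:
                pcs_frames.append(qc.compute_pcs(sub, n_pcs=k))
        if pcs_frames:
            pd.concat(pcs_frames).to_csv(
                outdir / "qc.pcs.tsv", sep="\t", index_label="sample_id"
            )

    elif stage == "gwas":
        g = cfg["gwas"]
        res = gwas.stratified_gwas(
            state["genotypes"], state["cohort"], g["trait"], g["model"],
            covariate_names=tuple(g["covariates"]), n_pcs=g["n_pcs"],
        )
        state["gwas"] = res
        for label, frame in res["per_stratum"].items():
            frame.to_csv(outdir / f"gwas.{label}.tsv", sep="\t", index=False)
        res["meta"].to_csv(outdir / "gwas.meta.tsv", sep="\t", index=False)
        gwas.manhattan_table(res["meta"]).to_csv(
            outdir / "gwas.manhattan.tsv", sep="\t", index=False
        )

    elif stage == "discover":
        d = cfg["discover"]
        cohort_stats = state["gwas"]["per_stratum"]["EA"]
        calls = discover.specific_variant_filter(
            cohort_stats, state["reference"], d["p_cohort"], d["p_reference"],
            d["ci_level"],
        )
        loci = discover.independent_loci(
            calls[calls["specific"]], state["genotypes"]
        )
        state["calls"] = calls
        calls.to_csv(outdir / "discover.calls.tsv", sep="\t", index=False)
        loci.to_csv(outdir / "discover.loci.tsv", sep="\t", index=False)

    elif stage == "prs":
        p = cfg["prs"]
        trait = p["trait"]
        models = {
            (trait, thr): prs.derive_prs_weights(
                state["reference"], thr, state["genotypes"],
                trait=trait, source="reference",
            )
            for thr in p["thresholds"]
        }
        state["models"] = models
        matrix = prs.prs_phenotype_matrix(
            models, state["genotypes"], state["cohort"],
            [t.name for t in state["traits"]],
        )
        matrix.to_csv(outdir / "prs.matrix.tsv", sep="\t", index=False)
        cv = prs.crossval_multiethnic(
            state["genotypes"], state["cohort"], state["reference"], trait,
            threshold=p["crossval_threshold"], k=p["k_folds"],
            seed=stage_seed(seed, "prs"), n_pcs=p["n_pcs"],
        )
        state["crossval"] = cv
        cv.cv.to_csv(outdir / "prs.crossval.tsv", sep="\t", index=False)
        disease = p["disease"]
        score_cols = {
            f"{trait}@{thr:g}": prs.score(m, state["genotypes"])
            for (_, thr), m in models.items()
        }
        scores = pd.DataFrame(score_cols)
        strat = prs.risk_stratification(
            scores,
            state["cohort"].set_index("sample_id")[disease],
            tuple(p["top_fractions"]),
        )
        state["stratification"] = strat
        strat.to_csv(outdir / "prs.stratification.tsv", sep="\t", index=False)

    elif stage == "report":
        summary = {
            "n_samples": int(state["genotypes"].n_samples),
            "n_variants": int(state["genotypes"].n_variants),
            "n_specific_calls": int(state["calls"]["specific"].sum()),
            "crossval_mean_r2_multi": state["crossval"].mean_adjusted_r2,
            "crossval_mean_r2_ea_only":
                float(state["crossval"].cv["r2_ea_only"].mean()),
            "max_or_top5": float(
                state["stratification"]
                .query("top_fraction == 0.05")["odds_ratio"].max()
            ),
        }
        (outdir / "report.summary.json").write_text(
            json.dumps(summary, indent=2)
        )
        state["summary"] = summary


def _load_stage(stage: str, outdir: Path, state: dict):
    """Re-hydrate stage outputs from disk for resumed runs."""
    if stage == "simulate":
        geno = GenotypeMatrix.from_tsv(outdir / "simulate.dosages.tsv")
        cohort = pd.read_csv(outdir / "simulate.cohort.tsv", sep="\t")
        strata = cohort.set_index("sample_id")["stratum"].reindex(geno.samples)
        geno.strata = strata
        sc = yaml.safe_load((outdir / "simulate.params.yaml").read_text())
        state.update(
            genotypes=geno,
            cohort=cohort,
            truth=pd.read_csv(outdir / "simulate.truth.tsv", sep="\t"),
            reference=pd.read_csv(outdir / "simulate.reference.tsv", sep="\t"),
            traits=[synthgen.TraitSpec(**t) for t in sc["traits"]],
        )
    elif stage == "qc":
        geno = GenotypeMatrix.from_tsv(outdir / "qc.dosages.tsv")
        strata = (
            state["cohort"].set_index("sample_id")["stratum"]
            .reindex(geno.samples)
        )
        geno.strata = strata
        state["genotypes"] = geno
        state["cohort"] = state["cohort"][
            state["cohort"]["sample_id"].isin(geno.samples)
        ].reset_index(drop=True)
    elif stage == "gwas":
        per = {}
        for f in outdir.glob("gwas.*.tsv"):
            label = f.name.split(".")[1]
            if label in ("meta", "manhattan"):
                continue
            per[label] = pd.read_csv(f, sep="\t")
        state["gwas"] = {
            "per_stratum": per,
            "meta": pd.read_csv(outdir / "gwas.meta.tsv", sep="\t"),
        }
    elif stage == "discover":
        state["calls"] = pd.read_csv(outdir / "discover.calls.tsv", sep="\t")
    else:
        # prs/report resumption recomputes (models are cheap to re-derive)
        raise RuntimeError("recompute")
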