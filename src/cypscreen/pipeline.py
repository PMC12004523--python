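"""End-to-end workflow: simulate -> curate -> featurize -> CV -> final
models -> screening funnel.

Four model bundles are produced (two sources x two feature panels), matching
the screening campaign's ensemble.  Every stage writes its report to the
artifacts directory, and a manifest records seeds, configuration and
dataset hashes; re-running the same configuration reproduces the funnel
report bit for bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import chemspace, io, modeling, screening
from .config import PipelineConfig
from .records import Label
from .synthetic import SyntheticConfig, generate_labeled_dataset, generate_screening_library
from .curation import curate


def _featurize(records, panel):
    if panel == "ecfp4_2048":
        return chemspace.ecfp4_block(records)
    return chemspace.physchem_block(records)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def train_models(config: PipelineConfig, outdir) -> dict:
    """Simulate, curate, cross-validate and train the four final bundles.

    Writes to ``outdir``: curated datasets and curation reports, the CV
    selection tables, held-out test metrics, cross-source metrics, and one
    manifest per bundle.  Returns the in-memory artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim, mod = config.simulation, config.modeling

    # --- simulate two sources -------------------------------------------
    datasets = {
        "balanced": SyntheticConfig.balanced(
            sim.n_balanced, label_noise=sim.label_noise,
            planted_rule=sim.planted_rule, n_scaffolds=sim.n_scaffolds,
            seed=sim.seed,
        ),
        "imbalanced": SyntheticConfig.imbalanced(
            sim.n_imbalanced, label_noise=sim.label_noise,
            planted_rule=sim.planted_rule, n_scaffolds=sim.n_scaffolds,
            seed=sim.seed + 1,
        ),
    }

    curated = {}
    for name, cfg in datasets.items():
        records, truth = generate_labeled_dataset(cfg)
        kept, report = curate(records)
        curated[name] = kept
        io.write_csv(kept, outdir / f"curated_{name}.csv")
        _json_dump({cid: t for cid, t in truth.items()}, outdir / f"truth_{name}.json")
        (outdir / f"curation_{name}.json").write_text(report.to_json())

    # --- featurize, cross-validate, train final bundles -----------------
    bundles = []
    cv_tables = {}
    test_metrics = {}
    for name, records in curated.items():
        y_all = np.array([1 if r.label is Label.ACTIVE else 0 for r in records])
        train, test = modeling.split_train_test(records, mod.test_fraction, seed=mod.seed)
        fps_train = chemspace.ecfp4_block(train).matrix
        y_train = np.array([1 if r.label is Label.ACTIVE else 0 for r in train])
        y_test = np.array([1 if r.label is Label.ACTIVE else 0 for r in test])
        for panel in ("ecfp4_2048", "physchem_2d"):
            tag = f"{name}_{panel}"
            block_train = _featurize(train, panel)
            medians = block_train.impute_nonfinite_()
            cv = modeling.cv_select(
                block_train.matrix, y_train, fps_train,
                grid=tuple(mod.grid), k=mod.k_folds, alpha=mod.alpha,
                similarity_floor=mod.similarity_floor,
                oversample_mode=mod.oversample_mode, seed=mod.seed,
                n_estimators=mod.n_estimators,
                compound_ids=[r.compound_id for r in train],
            )
            cv_tables[tag] = cv.as_table()
            # held-out evaluation of the chosen setting
            eval_bundle = modeling.train_final(
                block_train.matrix, y_train, cv.chosen, panel,
                oversample_mode=mod.oversample_mode, seed=mod.seed,
                n_estimators=mod.n_estimators, name=f"{tag}_train",
                impute_medians=medians,
            )
            block_test = _featurize(test, panel)
            block_test.impute_nonfinite_(medians)
            proba = eval_bundle.predict_proba_active(block_test.matrix)
            test_metrics[tag] = {
                "roc_auc": modeling.roc_auc(proba, y_test),
                "bedroc": modeling.bedroc(proba, y_test, alpha=mod.alpha),
                "chosen_max_features": str(cv.chosen),
                "cv_mean_bedroc": cv.chosen_mean_bedroc,
            }
            # final model on the full dataset for screening
            block_all = _featurize(records, panel)
            medians_all = block_all.impute_nonfinite_()
            bundles.append(
                modeling.train_final(
                    block_all.matrix, y_all, cv.chosen, panel,
                    oversample_mode=mod.oversample_mode, seed=mod.seed,
                    n_estimators=mod.n_estimators, name=tag,
                    impute_medians=medians_all,
                )
            )

    # cross-source evaluation: each final bundle on the other source
    cross_metrics = {}
    for bundle in bundles:
        source = bundle.name.split("_")[0]
        other = curated["imbalanced" if source == "balanced" else "balanced"]
        block = _featurize(other, bundle.panel)
        block.impute_nonfinite_(bundle.impute_medians)
        y_other = np.array([1 if r.label is Label.ACTIVE else 0 for r in other])
        cross_metrics[bundle.name] = modeling.cross_source_evaluate(
            bundle, block.matrix, y_other, alpha=mod.alpha
        )

    _json_dump(cv_tables, outdir / "cv_results.json")
    _json_dump(test_metrics, outdir / "test_metrics.json")
    _json_dump(cross_metrics, outdir / "cross_source_metrics.json")
    for bundle in bundles:
        _json_dump(bundle.manifest(), outdir / f"bundle_{bundle.name}.json")

    return {
        "curated": curated,
        "bundles": bundles,
        "cv_tables": cv_tables,
        "test_metrics": test_metrics,
        "cross_metrics": cross_metrics,
    }


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full workflow (training plus screening funnel)."""
    outdir = Path(outdir)
    sim, fun = config.simulation, config.funnel
    artifacts = train_models(config, outdir)
    curated, bundles = artifacts["curated"], artifacts["bundles"]

    # --- screening funnel ------------------------------------------------
    library, lib_truth = generate_screening_library(
        sim.library_decoys, sim.library_planted,
        SyntheticConfig(
            planted_rule=sim.planted_rule, seed=sim.seed + 2, foreign=True,
        ),
        motif_decoy_fraction=sim.motif_decoy_fraction,
    )
    actives = [r for recs in curated.values() for r in recs if r.label is Label.ACTIVE]
    known_fps = chemspace.ecfp4_block(actives).matrix
    funnel_cfg = screening.FunnelConfig(
        top_n=fun.top_n, p_min=fun.p_min, novelty_max_sim=fun.novelty_max_sim,
        diversity_sim=fun.diversity_sim, rotatable_bond_max=fun.rotatable_bond_max,
    )
    report = screening.run_funnel(library, bundles, known_fps, funnel_cfg)
    _json_dump(report.to_dict(), outdir / "funnel_report.json")
    _json_dump({cid: t for cid, t in lib_truth.items()}, outdir / "truth_library.json")
    io.write_csv(library, outdir / "library.csv")

    manifest = {
        "config": config.model_dump(mode="json"),
        "bundles": [b.manifest() for b in bundles],
        "funnel_counts": [[n, i, o] for n, i, o in report.counts()],
    }
    _json_dump(manifest, outdir / "manifest.json")

    artifacts.update(
        funnel_report=report, library_truth=lib_truth, library=library
    )
    return artifacts


def rebuild_bundles(artifacts_dir) -> list:
    """Retrain the final bundles from an artifacts directory's manifests.

    A bundle manifest (panel, hyperparameters, seeds, dataset hash) plus the
    curated dataset is sufficient to retrain a bit-identical model.
    """
    artifacts_dir = Path(artifacts_dir)
    bundles = []
    for path in sorted(artifacts_dir.glob("bundle_*.json")):
        entry = json.loads(path.read_text())
        source = entry["name"].split("_")[0]
        records, errors = io.read_compounds(artifacts_dir / f"curated_{source}.csv")
        if errors:
            raise ValueError(f"curated_{source}.csv has malformed rows: {errors[:3]}")
        y = np.array([1 if r.label is Label.ACTIVE else 0 for r in records])
        block = _featurize(records, entry["panel"])
        medians = block.impute_nonfinite_()
        if modeling.dataset_hash(block.matrix, y) != entry["dataset_hash"]:
            raise ValueError(f"dataset hash mismatch for bundle {entry['name']}")
        mf = entry["max_features"]
        mf = None if mf == "None" else (mf if mf == "sqrt" else float(mf))
        bundles.append(
            modeling.train_final(
                block.matrix, y, mf, entry["panel"],
                oversample_mode=entry["oversample_mode"], seed=entry["seed"],
                n_estimators=entry["n_estimators"], name=entry["name"],
                impute_medians=medians,
            )
        )
    return bundles


def known_active_fingerprints(artifacts_dir) -> np.ndarray:
    """ECFP4 matrix of all curated actives in an artifacts directory."""
    artifacts_dir = Path(artifacts_dir)
    actives = []
    for path in sorted(artifacts_dir.glob("curated_*.csv")):
        records, _ = io.read_compounds(path)
        actives += [r for r in records if r.label is Label.ACTIVE]
    return chemspace.ecfp4_block(actives).matrix
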