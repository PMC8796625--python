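"""End-to-end orchestration: simulate -> embed -> ensemble -> consensus ->
metrics/comparison/network, plus the independent EEG arm.

Every stage writes its artifacts into the run directory and records them in
``manifest.json`` together with the config hash and seeds, so a finished
run documents how to reproduce itself.  With ``resume=True`` a stage whose
artifacts already exist under the same config hash is skipped; deleting an
intermediate regenerates it and everything downstream.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io
from .analytics import build_transition_graph, compare_groups, metrics_table
from .arhmm import run_ensemble
from .config import PipelineConfig, validate_config
from .consensus import assign_syllables, cluster_signatures, linkage_to_newick
from .embedding import fit_pca, transform_sessions
from .synthetic import GapSpec, NoiseSpec, build_demo_model, make_cohort, simulate_eeg
from .types import DetectorSpec, FilterSpec

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]

_STAGES = ("simulate", "embed", "fit", "consensus", "metrics", "compare", "network", "ripples")


def _stage_files(out: Path) -> dict[str, list[Path]]:
    return {
        "simulate": [out / "sessions.h5", out / "cohort.csv", out / "ground_truth.json"],
        "embed": [out / "pca.json", out / "scores.h5"],
        "fit": [out / f"labels_fit.h5"],
        "consensus": [out / "syllables.h5", out / "signature_map.csv", out / "dendrogram.newick", out / "linkage.csv"],
        "metrics": [out / "metrics.csv"],
        "compare": [out / "comparison.csv"],
        "network": [out / "edges.csv"],
        "ripples": [out / "ripple_events.csv", out / "ripple_rates.csv"],
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path, resume: bool = False) -> Path:
    """Execute the pipeline, returning the run directory.

    A stage failure raises with the stage name and master seed in the
    message.  The EEG arm runs only when ``config.eeg_enabled``.
    """
    report = validate_config(config)
    report.raise_if_invalid()
    for w in report.warnings:
        logger.info("config: %s", w)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest_path = out / "manifest.json"
    manifest = {"config_hash": chash, "master_seed": config.master_seed, "stages": {}}
    if resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == chash:
            manifest = old

    files = _stage_files(out)

    def done(stage: str) -> bool:
        return (
            resume
            and manifest["stages"].get(stage, {}).get("complete", False)
            and all(p.exists() for p in files[stage])
        )

    def record(stage: str, t0: float, seeds=None) -> None:
        manifest["stages"][stage] = {
            "complete": True,
            "files": [p.name for p in files[stage]],
            "seconds": round(time.perf_counter() - t0, 3),
            "seeds": seeds,
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

    def invalidate_downstream(stage: str) -> None:
        i = _STAGES.index(stage)
        for s in _STAGES[i:]:
            manifest["stages"].pop(s, None)

    def run_stage(stage: str, fn) -> None:
        if done(stage):
            logger.info("stage %s: up to date, skipped", stage)
            return
        invalidate_downstream(stage)
        t0 = time.perf_counter()
        try:
            seeds = fn()
        except Exception as exc:  # noqa: BLE001 - add stage context
            raise RuntimeError(
                f"stage '{stage}' failed (master_seed={config.master_seed}): {exc}"
            ) from exc
        record(stage, t0, seeds)

    # --- behavioral arm -------------------------------------------------
    def _simulate():
        model = build_demo_model(K=config.sim_n_states, P=config.sim_n_dims, L=config.ar_order)
        gap = GapSpec(block_s=config.gap_block_s, gap_s_range=tuple(config.gap_s_range))
        cohort = make_cohort(
            model,
            genotype_effects=config.genotype_effects,
            n_per_genotype=config.n_per_genotype,
            minutes=config.session_minutes,
            fps=config.fps,
            gap_spec=gap,
            seed=config.master_seed,
        )
        sessions = [s for s, _ in cohort]
        io.save_sessions(files["simulate"][0], sessions)
        io.save_cohort_manifest(files["simulate"][1], sessions, files=["sessions.h5"] * len(sessions))
        io.save_ground_truth(files["simulate"][2], [gt for _, gt in cohort])
        return {"master": config.master_seed}

    run_stage("simulate", _simulate)
    sessions = io.load_sessions(files["simulate"][0])

    def _embed():
        n_comp = min(config.n_components, sessions[0].n_features)
        if n_comp != config.n_components:
            logger.info("n_components reduced to feature dimension %d", n_comp)
        pca = fit_pca(sessions, n_components=n_comp)
        io.save_pca_json(files["embed"][0], pca)
        io.save_scores(files["embed"][1], transform_sessions(pca, sessions), [s.valid_mask for s in sessions])
        return None

    run_stage("embed", _embed)
    scores, masks = io.load_scores(files["embed"][1])

    def _fit():
        ensemble = run_ensemble(
            scores,
            masks,
            K=config.n_states,
            L=config.ar_order,
            R=config.n_fits,
            master_seed=config.master_seed,
            max_iter=config.em_max_iter,
            tol=config.em_tol,
        )
        for r, fit in enumerate(ensemble.fits):
            io.save_model_json(out / f"model_fit{r}.json", fit.model)
        # one file with a (T, R) label matrix per session
        import h5py

        with h5py.File(files["fit"][0], "w") as f:
            for i in range(len(scores)):
                f.create_dataset(f"session_{i:03d}/labels", data=ensemble.labels_matrix(i))
        return {"fit_seeds": [f.seed for f in ensemble.fits]}

    run_stage("fit", _fit)

    import h5py

    with h5py.File(files["fit"][0], "r") as f:
        label_mats = [f[k]["labels"][()] for k in sorted(f.keys())]

    def _consensus():
        from .consensus import SignatureCatalog

        valid_rows = np.concatenate([m[m[:, 0] >= 0] for m in label_mats], axis=0)
        uniq, counts = np.unique(valid_rows, axis=0, return_counts=True)
        catalog = SignatureCatalog(signatures=uniq, counts=counts)
        n_syll = min(config.n_syllables, catalog.n_unique)
        if n_syll != config.n_syllables:
            logger.info("n_syllables reduced to %d unique signatures", n_syll)
        cluster_signatures(
            catalog,
            n_clusters=n_syll,
            linkage_method=config.linkage_method,
            count_weighted=config.count_weighted,
        )
        assignment = assign_syllables(label_mats, catalog)
        io.save_labels(files["consensus"][0], assignment.labels)
        import pandas as pd

        pd.DataFrame(
            {
                "signature": [",".join(map(str, row)) for row in catalog.signatures],
                "count": catalog.counts,
                "syllable": catalog.syllable_map,
            }
        ).to_csv(files["consensus"][1], index=False)
        if catalog.linkage_matrix is not None and catalog.linkage_matrix.size:
            files["consensus"][2].write_text(linkage_to_newick(catalog.linkage_matrix))
            pd.DataFrame(catalog.linkage_matrix, columns=["left", "right", "height", "size"]).to_csv(
                files["consensus"][3], index=False
            )
        else:
            files["consensus"][2].write_text(";")
            pd.DataFrame(columns=["left", "right", "height", "size"]).to_csv(files["consensus"][3], index=False)
        return None

    run_stage("consensus", _consensus)
    syllables = io.load_labels(files["consensus"][0])
    n_syll = int(max(lb.max() for lb in syllables)) + 1

    def _metrics():
        table = metrics_table(
            syllables,
            [s.valid_mask for s in sessions],
            fps=config.fps,
            n_syllables=n_syll,
            animal_ids=[s.animal_id for s in sessions],
            genotypes=[s.genotype for s in sessions],
        )
        table.to_csv(files["metrics"][0], index=False)
        return None

    run_stage("metrics", _metrics)

    import pandas as pd

    table = pd.read_csv(files["metrics"][0])

    def _compare():
        comp = compare_groups(table, alpha=config.alpha, p_adjust=config.p_adjust)
        comp.to_csv(files["compare"][0], index=False)
        return None

    run_stage("compare", _compare)

    def _network():
        edge_rows = []
        for geno in dict.fromkeys(s.genotype for s in sessions):
            idx = [i for i, s in enumerate(sessions) if s.genotype == geno]
            props = (
                table[table["genotype"] == geno]
                .groupby("syllable")["proportion"]
                .mean()
                .reindex(range(n_syll), fill_value=0.0)
                .to_numpy()
            )
            G, W = build_transition_graph(
                [syllables[i] for i in idx],
                [sessions[i].valid_mask for i in idx],
                n_syll,
                syllable_proportions=props,
                edge_threshold=config.edge_threshold,
            )
            io.save_graphml(out / f"network_{geno}.graphml", G)
            np.savetxt(out / f"transitions_{geno}.csv", W, delimiter=",", fmt="%.6f")
            for u, v, d in G.edges(data=True):
                edge_rows.append({"genotype": geno, "from": u, "to": v, "weight_pct": d["weight"]})
        pd.DataFrame(edge_rows).to_csv(files["network"][0], index=False)
        return None

    run_stage("network", _network)

    # --- EEG arm (independent) ------------------------------------------
    if config.eeg_enabled:

        def _ripples():
            from .ripples import detect_recording, summarize_rates

            rng = np.random.default_rng(config.master_seed + 777)
            rec, gt = simulate_eeg(
                duration_s=config.eeg_duration_s,
                fs=config.eeg_fs,
                channels=config.eeg_channels,
                background=NoiseSpec(),
                events=[],
                seed=int(rng.integers(2**31 - 1)),
            )
            io.save_eeg(out / "eeg.h5", rec)
            fspec = FilterSpec(band=(config.band_low_hz, config.band_high_hz), order=config.filter_order)
            dspec = DetectorSpec(
                min_oscillations=config.min_oscillations,
                amplitude_ratio=config.amplitude_ratio,
                baseline_window_ms=config.baseline_window_ms,
                merge_gap_ms=config.merge_gap_ms,
            )
            detections = detect_recording(rec, fspec, dspec)
            all_events = [e for evs in detections.values() for e in evs]
            io.events_to_frame(all_events, rec.fs).to_csv(files["ripples"][0], index=False)
            counts = {("synthetic", ch): len(evs) for ch, evs in detections.items()}
            summary = summarize_rates(counts, rec.duration_s / 60.0, {"synthetic": "synthetic"})
            summary.rates.to_csv(files["ripples"][1], index=False)
            return None

        run_stage("ripples", _ripples)

    return out
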