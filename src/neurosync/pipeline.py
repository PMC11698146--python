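"""End-to-end orchestration: simulate -> ISC -> NCI -> behavior.

A :class:`RunConfig` names the inputs (or asks for a simulated dataset), the
analysis parameters and an output directory; :func:`run_pipeline` executes
the stages in order, writes every stage's tables, and finishes with a JSON
manifest (parameters, seed, package version, input hashes, output hashes)
sufficient to reproduce the run bit-identically. Subject subsetting supports
sensitivity re-analyses (e.g. excluding medicated participants).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .datasets import GROUPS, IRI_SUBSCALES, SYMPTOMS, BehavioralTable
from . import io as nio
from .behav import epoch_mean_nci, isc_behavior_assoc, nci_behavior_assoc
from .isc import compare_groups, group_isc, max_stat_null, threshold_groups
from .nci import (
    rating_epochs,
    significant_runs,
    sliding_nci,
    spatial_specificity,
    window_group_test,
)
from .simulate import default_config, gen_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``data_dir``/``participants``/``networks``/``rating`` point at
    existing files, or ``simulate=True`` generates the default synthetic
    dataset in the output directory first.
    """

    out_dir: str | Path = "out"
    data_dir: str | Path | None = None
    participants: str | Path | None = None
    networks: str | Path | None = None
    rating: str | Path | None = None
    simulate: bool = False
    alpha: float = 0.05
    n_iter: int = 1000
    window: int = 10
    step: int = 1
    n_random: int = 200
    rating_threshold: float | None = None  # default: half of scale max
    seed: int = 0
    #: subject ids excluded before any analysis (sensitivity re-analysis).
    exclude_subjects: tuple[str, ...] = field(default_factory=tuple)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("data_dir", "participants", "networks", "rating"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name}: missing path {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "alpha": config.alpha,
            "n_iter": config.n_iter,
            "window": config.window,
            "step": config.step,
            "n_random": config.n_random,
            "exclude_subjects": list(config.exclude_subjects),
        },
        "stages": [],
        "inputs": {},
        "outputs": {},
        "complete": False,
    }
    stage = "setup"
    try:
        root = np.random.SeedSequence(config.seed)
        seed_sim, seed_null_a, seed_null_b, seed_spec = root.spawn(4)

        stage = "load"
        if config.simulate:
            sim_dir = out / "simulated"
            sim_dir.mkdir(exist_ok=True)
            ds = gen_dataset(default_config(seed=config.seed))
            for s in ds.subjects:
                nio.write_timeseries(sim_dir / f"{s.subject_id}.tsv", s)
            nio.write_participants(sim_dir / "participants.tsv", ds.behavior)
            nets = {n.name: _net_to_definition(n) for n in ds.truth.networks}
            member = np.concatenate([n.indices for n in nets.values()])
            pool = np.setdiff1d(np.arange(ds.subjects[0].n_units), member)
            nio.write_networks(sim_dir / "networks.tsv", list(nets.values()), pool)
            nio.write_rating(sim_dir / "rating.tsv", ds.rating)
            subjects, behavior, rating = ds.subjects, ds.behavior, ds.rating
        else:
            behavior = nio.read_participants(config.participants)
            subjects = nio.read_dataset_dir(config.data_dir, behavior)
            nets, pool = nio.read_networks(config.networks)
            rating = nio.read_rating(config.rating)
            for name in ("data_dir", "participants", "networks", "rating"):
                p = Path(getattr(config, name))
                if p.is_file():
                    manifest["inputs"][name] = _sha256(p)
        if config.exclude_subjects:
            subjects = [
                s for s in subjects if s.subject_id not in config.exclude_subjects
            ]
            behavior = behavior.subset([s.subject_id for s in subjects])
            logger.info(
                "subset filter: %d subject(s) excluded, %d remain",
                len(config.exclude_subjects), len(subjects),
            )
        manifest["n_subjects"] = len(subjects)
        manifest["stages"].append("load")

        stage = "isc"
        group_a, group_b = GROUPS
        res_a = group_isc(subjects, group_a)
        res_b = group_isc(subjects, group_b)
        null_a = max_stat_null(subjects, group_a, config.n_iter, seed_null_a)
        null_b = max_stat_null(subjects, group_b, config.n_iter, seed_null_b)
        mask = threshold_groups(res_a, res_b, null_a, null_b, config.alpha)
        unit_table, roi_table = compare_groups(res_a, res_b, mask, config.alpha)
        for res in (res_a, res_b):
            nio.write_map(out / f"isc_mean_{res.group}.tsv", res.stat)
        pd.DataFrame({"max_stat": null_a.values}).to_csv(
            out / f"null_{group_a}.tsv", sep="\t", index=False
        )
        pd.DataFrame({"max_stat": null_b.values}).to_csv(
            out / f"null_{group_b}.tsv", sep="\t", index=False
        )
        unit_table.to_csv(out / "group_contrast.tsv", sep="\t", index=False)
        roi_out = roi_table.copy()
        roi_out["units"] = roi_out["units"].map(
            lambda u: ",".join(map(str, u))
        )
        roi_out.to_csv(out / "roi_table.tsv", sep="\t", index=False)
        manifest["stages"].append("isc")
        logger.info(
            "isc: thresholds %.4f/%.4f, %d unit(s) in joint mask, %d ROI(s)",
            res_a.threshold, res_b.threshold, int(mask.sum()), len(roi_table),
        )

        stage = "nci"
        net_list = list(nets.values())
        if len(net_list) < 2:
            raise ValueError("need at least two networks for the NCI stage")
        na, nb = net_list[0], net_list[1]
        curves = {
            na.name: na,
            nb.name: nb,
            f"{na.name}-{nb.name}": (na, nb),
        }
        threshold = (
            config.rating_threshold
            if config.rating_threshold is not None
            else rating.scale_max / 2.0
        )
        epochs = rating_epochs(rating, threshold, config.window, config.step)
        # runs shorter than one window carry no analysis windows; skip them
        epochs = [ep for ep in epochs if len(ep.windows)]
        by_group = {
            g: [s for s in subjects if s.group == g] for g in (group_a, group_b)
        }
        epoch_tables = []
        for label, networks in curves.items():
            series = {
                g: [
                    sliding_nci(s, networks, config.window, config.step)
                    for s in by_group[g]
                ]
                for g in (group_a, group_b)
            }
            wt = window_group_test(series[group_a], series[group_b], epochs=epochs)
            # spatial specificity for the windows significant after FDR
            sig_windows = wt.index[wt["q"] < config.alpha]
            for wi in sig_windows:
                wt.loc[wi, "specificity"] = spatial_specificity(
                    subjects,
                    group_a,
                    group_b,
                    int(wt.loc[wi, "window_start"]),
                    config.window,
                    networks,
                    pool,
                    n_random=config.n_random,
                    seed=np.random.default_rng(
                        seed_spec.spawn(1)[0]
                    ),
                )
            wt.to_csv(out / f"window_test_{label}.tsv", sep="\t", index=False)
            runs = significant_runs(wt, config.alpha)
            runs.to_json(out / f"runs_{label}.json", orient="records")
            if epochs:
                for g in (group_a, group_b):
                    epoch_tables.append(epoch_mean_nci(series[g], epochs))
        manifest["stages"].append("nci")

        stage = "behav"
        measures = [m for m in IRI_SUBSCALES if m in behavior.table.columns]
        if len(roi_table):
            assoc = isc_behavior_assoc(res_a, roi_table, behavior, measures)
            assoc.to_csv(out / "isc_behavior_assoc.tsv", sep="\t", index=False)
        if epoch_tables:
            epoch_nci = pd.concat(epoch_tables, ignore_index=True)
            ids_a = set(s.subject_id for s in by_group[group_a])
            table_a = epoch_nci[epoch_nci["subject_id"].isin(ids_a)]
            assoc_nci = nci_behavior_assoc(table_a, behavior, measures)
            assoc_nci.to_csv(out / "nci_behavior_assoc.tsv", sep="\t", index=False)
        manifest["stages"].append("behav")
        manifest["complete"] = True
    except Exception as exc:  # annotate which stage failed, keep the cause
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for p in sorted(out.rglob("*.tsv")):
        manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _net_to_definition(spec) -> "NetworkDefinition":
    from .datasets import NetworkDefinition

    return NetworkDefinition(name=spec.name, indices=np.asarray(spec.members, int))
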