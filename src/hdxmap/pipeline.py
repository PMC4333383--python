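"""End-to-end pipeline: simulate -> uptake -> diff -> ex1 -> map.

Each stage is a plain function operating on in-memory objects; the
orchestrator wires them together, writes the output tables, and keeps a
machine-readable run log (versions, seeds, thresholds, per-stage record
counts).  Any stage failure aborts with the stage name attached.
"""
from __future__ import annotations

import json
import logging
import platform
import sys
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .constants import ISOTOPE_SPACING
from .diffstats import DifferentialRecord, compare_states
from .envelopes import (
    IsotopicEnvelope,
    RegimeCall,
    centroid_mass,
    classify_exchange_regime,
    deconvolve_deuteration,
    natural_isotope_distribution,
)
from .io import (
    PipelineConfig,
    write_annotation_track,
    write_differential_table,
    write_envelope_tsv,
    write_peptide_table,
    write_uptake_tables,
    write_woods_table,
)
from .mapping import AnnotationTrack, consolidate_residue, infer_interface, sequence_coverage
from .peptides import PeptideID, max_exchangeable
from .studies import FIXTURES, build_fixture_study
from .synthetic import StudyDataset
from .uptake import UptakeRecord, UptakeValue, aggregate_replicates, compute_uptake, compute_uptake_fd

log = logging.getLogger("hdxmap")

__all__ = ["PipelineError", "run_pipeline", "uptake_stage", "differential_stage", "ex1_stage"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _theoretical_centroid(peptide: PeptideID) -> float:
    profile = natural_isotope_distribution(peptide.sequence)
    w = profile.probs / profile.probs.sum()
    return profile.monoisotopic_mass + ISOTOPE_SPACING * float(
        (np.arange(w.size) * w).sum()
    )


# --------------------------------------------------------------------------
# uptake stage
# --------------------------------------------------------------------------

def uptake_stage(
    envelopes: list[IsotopicEnvelope],
    config: PipelineConfig,
) -> tuple[list[UptakeRecord], list[dict]]:
    """Centroid every envelope and compute corrected uptake.

    The undeuterated baseline is the measured t0 envelope of the *same
    replicate* (falling back to the state's mean t0 when absent), or the
    theoretical undeuterated centroid when ``config.baseline ==
    'theoretical'``.  Replicate matching keeps baseline noise inside the
    per-replicate variance, which is what downstream significance tests
    assume.
    """
    by_cell: dict[tuple, dict] = defaultdict(lambda: {"t0": {}, "fd": {}, "exch": {}})
    for env in envelopes:
        cell = by_cell[(env.peptide.key(), env.state)]
        cell["peptide"] = env.peptide
        c = centroid_mass(env)
        if env.kind == "t0":
            cell["t0"][env.replicate] = c
        elif env.kind == "fd":
            cell["fd"][env.replicate] = c
        else:
            cell["exch"][(env.time_s, env.replicate)] = c

    aggregated: list[UptakeRecord] = []
    replicate_rows: list[dict] = []
    for (pkey, state), cell in sorted(by_cell.items()):
        peptide: PeptideID = cell["peptide"]
        n_exch = max_exchangeable(peptide.sequence, config.n_term_skip)
        if n_exch == 0:
            log.warning("skipping %s: no exchangeable amides", peptide.label)
            continue
        t0_map = cell["t0"]
        t0_mean = float(np.mean(list(t0_map.values()))) if t0_map else None
        theo = _theoretical_centroid(peptide)

        def baseline(rep: int) -> float:
            if config.baseline == "theoretical" or t0_mean is None:
                return theo
            return t0_map.get(rep, t0_mean)

        by_time: dict[float, list[UptakeValue]] = defaultdict(list)
        fd_by_time: dict[float, list[float]] = defaultdict(list)
        for (t, rep), c in sorted(cell["exch"].items()):
            value = compute_uptake(c, baseline(rep), n_exch, config.f_D, config.recovery)
            by_time[t].append(value)
            fd_centroid = cell["fd"].get(rep)
            if fd_centroid is not None and fd_centroid > baseline(rep):
                fd_by_time[t].append(compute_uptake_fd(c, baseline(rep), fd_centroid))
            replicate_rows.append(
                {
                    "peptide_id": peptide.label,
                    "protein": peptide.protein,
                    "start": peptide.start,
                    "end": peptide.end,
                    "state": state,
                    "time_s": t,
                    "replicate": rep,
                    "d_abs": round(value.d_abs, 5),
                    "d_percent": round(value.d_percent, 5),
                }
            )
        for t, values in sorted(by_time.items()):
            aggregated.append(
                aggregate_replicates(peptide, state, t, values, fd_by_time.get(t))
            )
    return aggregated, replicate_rows


# --------------------------------------------------------------------------
# differential stage
# --------------------------------------------------------------------------

def differential_stage(
    replicate_rows: list[dict],
    peptides: list[PeptideID],
    config: PipelineConfig,
    states: tuple[str, ...],
) -> list[DifferentialRecord]:
    """ANOVA/Tukey comparison of every peptide across the given states."""
    lookup = {(p.protein, p.start, p.end): p for p in peptides}
    per_peptide: dict[tuple, dict[str, dict[float, list[float]]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(list))
    )
    for row in replicate_rows:
        key = (row["protein"], row["start"], row["end"])
        per_peptide[key][row["state"]][row["time_s"]].append(row["d_percent"])
    records: list[DifferentialRecord] = []
    for key in sorted(per_peptide):
        pep = lookup.get(key)
        if pep is None:
            continue
        table = per_peptide[key]
        if not set(states) <= set(table):
            continue
        records.extend(
            compare_states(
                pep,
                {s: table[s] for s in states},
                states,
                delta_min=config.delta_min,
                alpha=config.alpha,
            )
        )
    return records


# --------------------------------------------------------------------------
# EX1 stage
# --------------------------------------------------------------------------

def ex1_stage(
    envelopes: list[IsotopicEnvelope],
    config: PipelineConfig,
    rng: np.random.Generator,
) -> dict[tuple, RegimeCall]:
    """Classify the exchange regime of every peptide x state.

    Replicate envelopes at each time point are deconvolved individually and
    their deuteration distributions averaged before mixture fitting, which
    suppresses intensity noise without blurring genuine bimodality.
    """
    grouped: dict[tuple, dict[float, list[np.ndarray]]] = defaultdict(lambda: defaultdict(list))
    peptides: dict[tuple, PeptideID] = {}
    for env in envelopes:
        if env.kind != "exchange":
            continue
        key = (env.peptide.key(), env.state)
        peptides[key] = env.peptide
        n_exch = max_exchangeable(env.peptide.sequence, config.n_term_skip)
        profile = natural_isotope_distribution(env.peptide.sequence)
        dist, _ = deconvolve_deuteration(env, profile, n_exch)
        grouped[key][env.time_s].append(dist)

    calls: dict[tuple, RegimeCall] = {}
    for key, series in sorted(grouped.items()):
        mean_series = {t: np.mean(np.stack(d), axis=0) for t, d in series.items()}
        calls[key] = classify_exchange_regime(
            mean_series,
            delta_bic_min=config.ex1_delta_bic,
            min_separation=config.ex1_min_separation,
            min_weight=config.ex1_min_weight,
            min_dprime=config.ex1_min_dprime,
            n_restarts=config.ex1_restarts,
            pseudo_n=config.ex1_pseudo_n,
            rng=rng,
        )
    return calls


# --------------------------------------------------------------------------
# orchestrator
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run simulate -> uptake -> diff -> ex1 -> map and write all tables.

    Returns a dict with the output paths and the key in-memory results.
    Identical config + seed produces byte-identical numeric outputs.
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    counts: dict[str, int] = {}

    stage = "simulate"
    try:
        if config.fixture not in FIXTURES:
            raise ValueError(
                f"unknown fixture {config.fixture!r}; available: {sorted(FIXTURES)}"
            )
        fixture = FIXTURES[config.fixture]()
        states = (fixture.state_apo, fixture.state_bound)
        study: StudyDataset = build_fixture_study(fixture, config.design(states))
        log.info("[simulate] %d envelopes, %d peptides", len(study.envelopes), len(study.peptides))
        counts["envelopes"] = len(study.envelopes)
        counts["peptides"] = len(study.peptides)
        write_peptide_table(out / "peptides.csv", study.peptides, chash)
        write_envelope_tsv(out / "envelopes.tsv", study.envelopes, chash)
        write_annotation_track(out / "annotations.tsv", fixture.annotations)
        with open(out / "manifest.json", "w") as fh:
            json.dump({"config": chash, **study.manifest}, fh, indent=1)

        stage = "uptake"
        aggregated, replicate_rows = uptake_stage(study.envelopes, config)
        counts["uptake_records"] = len(aggregated)
        log.info("[uptake] %d aggregated records", len(aggregated))
        write_uptake_tables(out, aggregated, replicate_rows, chash)

        stage = "diff"
        records = differential_stage(replicate_rows, study.peptides, config, states)
        counts["differential_records"] = len(records)
        log.info("[diff] %d comparisons", len(records))
        write_differential_table(out / "differential.csv", records, chash)
        write_woods_table(out / "woods.csv", records, chash)

        stage = "ex1"
        rng = np.random.default_rng(
            None if config.seed is None else config.seed + 10_007
        )
        calls = ex1_stage(study.envelopes, config, rng)
        counts["regime_calls"] = len(calls)
        import pandas as pd

        label_of = {p.key(): p.label for p in study.peptides}
        ex1_rows = [
            {
                "peptide_id": label_of.get(pkey, f"{pkey[1]}-{pkey[2]}"),
                "protein": pkey[0],
                "start": pkey[1],
                "end": pkey[2],
                "charge": pkey[3],
                "state": state,
                "regime": call.regime,
                "qualifying_times_s": ";".join(f"{t:g}" for t in call.qualifying_times),
            }
            for (pkey, state), call in sorted(calls.items())
        ]
        frame = pd.DataFrame(ex1_rows)
        with open(out / "ex1.csv", "w", newline="") as fh:
            fh.write(f"# config: {chash}\n")
            frame.to_csv(fh, index=False)

        stage = "map"
        length = fixture.length
        coverage, redundancy = sequence_coverage(study.peptides, length)
        profile = consolidate_residue(records, length)
        cov_rows = pd.DataFrame(
            {
                "residue": np.arange(1, length + 1),
                "redundancy": redundancy,
                "mean_delta_d": np.round(profile, 4),
            }
        )
        with open(out / "coverage.csv", "w", newline="") as fh:
            fh.write(f"# config: {chash}\n# coverage_fraction: {coverage:.4f}\n")
            cov_rows.to_csv(fh, index=False)

        report = infer_interface(
            records, fixture.annotations,
            rotation_per_monomer_deg=config.rotation_per_monomer_deg,
        )
        counts["interface_peptides"] = report.n_interface
        with open(out / "interface.json", "w") as fh:
            json.dump(
                {
                    "config": chash,
                    "n_interface": report.n_interface,
                    "n_front": report.n_front,
                    "n_back": report.n_back,
                    "interface": [
                        {
                            "peptide": ip.peptide.label,
                            "face": ip.face,
                            "mean_delta_d": round(ip.mean_delta_d, 4),
                            "dual_rna_binding": ip.dual_rna_binding,
                        }
                        for ip in report.interface
                    ],
                    "footprint": [p.label for p in report.footprint],
                    "rotation_per_monomer_deg": report.rotation_per_monomer_deg,
                    "monomers_per_repeat": report.monomers_per_repeat,
                    "monomers_per_repeat_rounded": report.monomers_per_repeat_rounded,
                },
                fh,
                indent=1,
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    run_log = {
        "hdxmap_version": __version__,
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "config_hash": chash,
        "seed": config.seed,
        "thresholds": {
            "alpha": config.alpha,
            "delta_min": config.delta_min,
            "ex1_delta_bic": config.ex1_delta_bic,
            "ex1_min_separation": config.ex1_min_separation,
            "ex1_min_weight": config.ex1_min_weight,
        },
        "record_counts": counts,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1)

    return {
        "outdir": out,
        "coverage": coverage,
        "records": records,
        "interface": report,
        "regime_calls": calls,
        "counts": counts,
    }
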