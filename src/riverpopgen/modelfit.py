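"""Goodness of fit between simulated and empirical node statistics.

If a simulation reproduced the data exactly, points (empirical, simulated)
would fall on the 1:1 line.  The fit measures quantify departure from that
line by the perpendicular (orthogonal) offset of each point:

    offset_k = (sim_k - emp_k) / sqrt(2)

signed positive when the simulation overestimates.  Summaries:

* SPO  — sum of absolute offsets (overall spread; larger = poorer fit),
* MPO  — median of absolute offsets (robust to outlier nodes),
* DMPO — median of the signed offsets (direction of mis-fit).

Scenario grids are compared parameter-wise: a focal parameter value "wins"
a context (a combination of the remaining parameters x response x species x
measure in {SPO, MPO}) against an alternative value when its measure is
strictly smaller.  The win fraction over all contexts and alternatives
summarizes whether the focal value is generally superior (> 0.5).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "perpendicular_offsets",
    "spo",
    "mpo",
    "dmpo",
    "scenario_fit",
    "simulated_node_statistics",
    "fst_fit_summary",
    "parameter_win_fraction",
    "ComparisonResult",
]

SQRT2 = math.sqrt(2.0)


def perpendicular_offsets(emp, sim) -> np.ndarray:
    """Signed perpendicular distances of (emp, sim) points to the 1:1 line."""
    emp = np.asarray(emp, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if emp.shape != sim.shape:
        raise ValueError(
            f"length mismatch: {emp.shape} empirical vs {sim.shape} simulated"
        )
    return (sim - emp) / SQRT2


def _require_nonempty(offsets) -> np.ndarray:
    arr = np.asarray(offsets, dtype=float)
    if arr.size == 0:
        raise ValueError("no offsets given")
    return arr


def spo(offsets) -> float:
    """Sum of absolute perpendicular offsets."""
    return float(np.sum(np.abs(_require_nonempty(offsets))))


def mpo(offsets) -> float:
    """Median of absolute perpendicular offsets."""
    return float(np.median(np.abs(_require_nonempty(offsets))))


def dmpo(offsets) -> float:
    """Median of the signed perpendicular offsets (direction of mis-fit)."""
    return float(np.median(_require_nonempty(offsets)))


def scenario_fit(
    empirical: pd.DataFrame,
    simulated: pd.DataFrame,
    responses=("AR", "Ho", "He"),
    scenario_cols=("d", "W", "k_mode", "mut_model"),
) -> pd.DataFrame:
    """Per-scenario fit summaries against matched empirical statistics.

    Parameters
    ----------
    empirical
        One row per (node_id, species) with response columns.  The species
        factor lives on the empirical side: every scenario is compared to
        each species' node subset separately.
    simulated
        One row per (scenario x node_id) carrying the scenario columns and
        the same response columns (replicate means); matched on node_id.

    Returns one row per (scenario, response, species) with n_points, SPO,
    MPO and DMPO.  A simulated table missing an empirical node is an error:
    fits must be computed over the full empirical node set.
    """
    scenario_cols = [c for c in scenario_cols if c in simulated.columns]
    emp = empirical.reset_index() if empirical.index.nlevels > 1 else empirical
    rows = []
    for key, sub in simulated.groupby(scenario_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        for species, emp_sp in emp.groupby("species", sort=True):
            missing = set(emp_sp["node_id"]) - set(sub["node_id"])
            if missing:
                raise ValueError(
                    f"simulation output missing empirical node(s): {sorted(missing)[:5]}"
                )
            merged = emp_sp.merge(
                sub, on="node_id", suffixes=("_emp", "_sim")
            )
            for resp in responses:
                off = perpendicular_offsets(
                    merged[f"{resp}_emp"], merged[f"{resp}_sim"]
                )
                off = off[~np.isnan(off)]
                rows.append(
                    dict(zip(scenario_cols, key))
                    | {
                        "response": resp,
                        "species": species,
                        "n_points": int(off.size),
                        "SPO": spo(off),
                        "MPO": mpo(off),
                        "DMPO": dmpo(off),
                    }
                )
    return pd.DataFrame(rows)


def simulated_node_statistics(
    results,
    params,
    node_subset=None,
    sample_sizes=None,
    g: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicate-averaged per-node AR/Ho/He for one simulated scenario.

    Parameters
    ----------
    results
        List of ``ReplicateResult`` from :func:`riverpopgen.simulator.run`.
    params
        The scenario's ``SimulationParams`` (its d, W, k_mode, mut_model
        become scenario columns).
    node_subset
        Node ids to report (default: all occupied nodes).
    sample_sizes
        Optional mapping node_id -> n used to subsample each simulated node
        to the matching empirical sample size before computing statistics,
        so rarefaction-sensitive quantities are comparable.
    g
        Rarefaction size passed through to allelic richness (default:
        rarefy to the smallest cell of the — possibly subsampled — table).

    Extinct replicates are skipped; statistics are averaged over the
    surviving replicates per node.
    """
    from .popgen import node_diversity, subsample

    per_rep = []
    for res in results:
        if res.genotypes is None:
            continue
        gt = res.genotypes
        if node_subset is not None:
            keep = gt.data["node_id"].isin(set(node_subset))
            gt = type(gt)(gt.data[keep].reset_index(drop=True), loci=gt.loci)
        if sample_sizes is not None:
            gt = subsample(gt, dict(sample_sizes), seed=seed)
        div = node_diversity(gt, g=g).reset_index()
        div["replicate"] = res.replicate
        per_rep.append(div)
    if not per_rep:
        raise ValueError("all replicates extinct: no statistics to report")
    stats = (
        pd.concat(per_rep, ignore_index=True)
        .groupby("node_id", sort=True)[["AR", "Ho", "He"]]
        .mean()
        .reset_index()
    )
    stats["d"] = params.d
    stats["W"] = params.W
    stats["k_mode"] = params.k_mode
    stats["mut_model"] = params.mut_model
    return stats


def fst_fit_summary(emp_fst: pd.DataFrame, sim_fst: pd.DataFrame) -> dict:
    """SPO/MPO/DMPO between two pairwise-F_ST matrices over the node pairs
    present in the empirical matrix (upper triangle, matched labels)."""
    nodes = list(emp_fst.index)
    sim = sim_fst.loc[nodes, nodes].to_numpy()
    emp = emp_fst.to_numpy()
    iu = np.triu_indices(len(nodes), k=1)
    off = perpendicular_offsets(emp[iu], sim[iu])
    off = off[~np.isnan(off)]
    return {
        "n_points": int(off.size),
        "SPO": spo(off),
        "MPO": mpo(off),
        "DMPO": dmpo(off),
    }


@dataclass(frozen=True)
class ComparisonResult:
    """Win count for one focal value of one scenario parameter."""

    parameter: str
    focal_value: object
    wins: int
    ties: int
    total: int
    skipped_contexts: int

    @property
    def win_fraction(self) -> float:
        return self.wins / self.total if self.total else float("nan")


def parameter_win_fraction(
    fits: pd.DataFrame,
    parameter: str,
    focal_value,
    measures=("SPO", "MPO"),
) -> ComparisonResult:
    """Fraction of pairwise scenario comparisons the focal value wins.

    For every context — a combination of the *other* scenario parameters x
    response x species x measure — the focal scenario is compared with each
    alternative value of ``parameter``; it wins when its measure is strictly
    smaller.  Exact ties count as non-wins for both sides and are reported.
    Contexts with missing grid cells are skipped and counted.
    """
    param_cols = [
        c for c in ("d", "W", "k_mode", "mut_model") if c in fits.columns
    ]
    if parameter not in param_cols:
        raise KeyError(f"unknown scenario parameter {parameter!r}")
    other = [c for c in param_cols if c != parameter]
    values = sorted(fits[parameter].unique(), key=str)
    if focal_value not in values:
        raise ValueError(f"focal value {focal_value!r} not present in the grid")
    alternatives = [v for v in values if v != focal_value]
    contexts = fits[other + ["response", "species"]].drop_duplicates()
    indexed = fits.set_index(param_cols + ["response", "species"])

    def lookup(pval, ctx):
        key = []
        for c in param_cols:
            key.append(pval if c == parameter else ctx[c])
        key += [ctx["response"], ctx["species"]]
        try:
            return indexed.loc[tuple(key)]
        except KeyError:
            return None

    wins = ties = total = skipped = 0
    for _, ctx in contexts.iterrows():
        focal_row = lookup(focal_value, ctx)
        for alt in alternatives:
            alt_row = lookup(alt, ctx)
            if focal_row is None or alt_row is None:
                skipped += len(measures)
                continue
            for meas in measures:
                total += 1
                diff = float(focal_row[meas]) - float(alt_row[meas])
                if diff < 0:
                    wins += 1
                elif diff == 0:
                    ties += 1
    return ComparisonResult(
        parameter=parameter,
        focal_value=focal_value,
        wins=wins,
        ties=ties,
        total=total,
        skipped_contexts=skipped,
    )
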