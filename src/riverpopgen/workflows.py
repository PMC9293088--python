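"""High-level study pipelines composing the analysis modules.

These are the end-to-end recipes: compute site diversity and
isolation-by-distance summaries from a genotype table on a network
(:func:`empirical_summary`), run a full simulation scenario grid
(:func:`scenario_grid`, :func:`run_scenario_grid`), and score every
scenario against reference statistics with perpendicular-offset measures
(:func:`fit_study`).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import modelfit as mf
from . import popgen as pg
from .network import RiverNetwork, instream_distance_matrix
from .simulator import SimulationParams, run

__all__ = [
    "empirical_summary",
    "scenario_grid",
    "run_scenario_grid",
    "min_observed_cell",
    "fit_study",
]


def empirical_summary(
    gt: pg.GenotypeTable,
    net: RiverNetwork | None = None,
    min_n: int = 15,
    mantel_perms: int = 1000,
    seed: int = 0,
) -> dict:
    """Site-diversity and isolation-by-distance summary per species.

    Applies the minimum-sample-size inclusion filter, computes per-node
    AR/Ho/He/F_IS (AR rarefied per species) and pairwise Nei F_ST, and — when
    a network is given — the Mantel correlation between genetic and instream
    distance plus the power-term scan of the isolation-by-distance model
    (species pooled, with interaction, negative F_ST values zeroed).

    Returns a dict with keys ``diversity`` (DataFrame), ``fst`` (dict of
    species -> matrix), ``per_species`` (summary means), and when a network
    is given ``mantel`` (species -> (r, p)) and ``ibd_power``.
    """
    gt = pg.filter_nodes(gt, min_n=min_n)
    diversity = []
    fst: dict = {}
    per_species: dict = {}
    mantel: dict = {}
    pair_frames = []
    for sp in gt.species_list():
        sub = gt.subset_species(sp)
        div = pg.node_diversity(sub)
        diversity.append(div.reset_index())
        mat = pg.pairwise_nei_fst(sub)
        fst[sp] = mat
        iu = np.triu_indices(len(mat), k=1)
        vals = mat.to_numpy()[iu]
        per_species[sp] = {
            "n_nodes": len(mat),
            "n_individuals": sub.n_individuals,
            "AR": float(div["AR"].mean()),
            "Ho": float(div["Ho"].mean()),
            "He": float(div["He"].mean()),
            "Fis": float(div["Fis"].mean()),
            "mean_fst": float(np.nanmean(vals)) if vals.size else float("nan"),
        }
        if net is not None and len(mat) >= 3:
            dmat = instream_distance_matrix(net, list(mat.index))
            mantel[sp] = pg.mantel_test(
                dmat.to_numpy(), mat.to_numpy(), n_perm=mantel_perms, seed=seed
            )
            pairs = pg.fst_long(mat)
            pairs["distance"] = [
                dmat.loc[a, b] for a, b in zip(pairs["node_a"], pairs["node_b"])
            ]
            pairs["species"] = sp
            pair_frames.append(pairs)
    out = {
        "diversity": pd.concat(diversity, ignore_index=True),
        "fst": fst,
        "per_species": per_species,
    }
    if mantel:
        out["mantel"] = mantel
    if pair_frames:
        from .regression import power_scan

        pairs = pd.concat(pair_frames, ignore_index=True).dropna(subset=["fst"])
        species_arg = (
            pairs["species"].to_numpy() if pairs["species"].nunique() == 2 else None
        )
        best_p, fit, curve = power_scan(
            pairs["fst"].to_numpy(), pairs["distance"].to_numpy(), species_arg
        )
        out["ibd_power"] = best_p
        out["ibd_fit"] = fit
        out["ibd_curve"] = curve
    return out


def scenario_grid(
    base: SimulationParams,
    d_values=(0.001, 0.01, 0.1),
    W_values=(0.0, 0.5, 1.0),
    k_modes=("fixed", "scaled"),
    mut_models=("stepwise",),
) -> list[SimulationParams]:
    """Full-orthogonal scenario grid (default: the 3 x 3 x 2 local-diversity
    grid for one mutational model).  Every scenario derives its own seed
    from the base seed so replicate streams never collide across scenarios."""
    out = []
    i = 0
    for mut in mut_models:
        for d in d_values:
            for W in W_values:
                for k_mode in k_modes:
                    out.append(
                        replace(
                            base,
                            d=d,
                            W=W,
                            k_mode=k_mode,
                            mut_model=mut,
                            seed=(base.seed + 7919 * (i + 1)) % (2**31),
                        )
                    )
                    i += 1
    return out


def min_observed_cell(gt: pg.GenotypeTable) -> int:
    """Smallest number of observed gene copies over all (node, species,
    locus) cells — the upper bound for a shared rarefaction size."""
    best = None
    for (_, _), grp in gt.groups():
        for loc in gt.loci:
            obs = 2 * int((grp[f"{loc}_a1"] != pg.MISSING).sum())
            if obs and (best is None or obs < best):
                best = obs
    if best is None:
        raise ValueError("no observed calls in table")
    return best


def run_scenario_grid(
    net: RiverNetwork,
    scenarios: list[SimulationParams],
    node_subset=None,
    sample_sizes=None,
    g: int | str | None = "auto",
    g_cap: int = 20,
    extra_tables=(),
    seed: int | None = None,
    record_every: int = 1000,
) -> tuple[pd.DataFrame, int | None]:
    """Run every scenario and return stacked per-node simulated statistics
    (replicate means) plus the rarefaction size used, ready for
    :func:`riverpopgen.modelfit.scenario_fit`.

    ``g="auto"`` (default) harmonizes the rarefaction size to the smallest
    observed cell across all scenario replicates and any ``extra_tables``
    (e.g. the empirical genotype table), capped at ``g_cap`` — the
    rarefy-to-minimum convention applied across the whole comparison.
    """
    prepared: list[tuple[SimulationParams, list[pg.GenotypeTable]]] = []
    for params in scenarios:
        results = run(net, params, record_every=record_every)
        reps = []
        for res in results:
            if res.genotypes is None:
                continue
            gt = res.genotypes
            if node_subset is not None:
                keep = gt.data["node_id"].isin(set(node_subset))
                gt = pg.GenotypeTable(
                    gt.data[keep].reset_index(drop=True), loci=gt.loci
                )
            if sample_sizes is not None:
                gt = pg.subsample(gt, dict(sample_sizes), seed=seed)
            reps.append(gt)
        if not reps:
            raise ValueError(
                f"all replicates extinct for scenario {params.scenario_label()}"
            )
        prepared.append((params, reps))
    if g == "auto":
        cells = [min_observed_cell(t) for _, reps in prepared for t in reps]
        cells += [min_observed_cell(t) for t in extra_tables]
        g = min(g_cap, min(cells))
    frames = []
    for params, reps in prepared:
        per_rep = []
        for i, gt in enumerate(reps):
            div = pg.node_diversity(gt, g=g).reset_index()
            per_rep.append(div)
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
        frames.append(stats)
    return pd.concat(frames, ignore_index=True), g


def fit_study(
    empirical: pd.DataFrame,
    simulated: pd.DataFrame,
    parameters=("d", "W", "k_mode"),
) -> dict:
    """Scenario fits plus the parameter-wise win-fraction table.

    Returns ``{"fits": DataFrame, "comparisons": DataFrame}`` where the
    comparisons table has one row per (parameter, focal value) with wins,
    ties, total and win fraction.
    """
    fits = mf.scenario_fit(empirical, simulated)
    rows = []
    for parameter in parameters:
        if parameter not in fits.columns:
            continue
        for value in sorted(fits[parameter].unique(), key=str):
            res = mf.parameter_win_fraction(fits, parameter, value)
            rows.append(
                {
                    "parameter": parameter,
                    "focal_value": value,
                    "wins": res.wins,
                    "ties": res.ties,
                    "total": res.total,
                    "win_fraction": res.win_fraction,
                }
            )
    return {"fits": fits, "comparisons": pd.DataFrame(rows)}
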