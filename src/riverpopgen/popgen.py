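"""Microsatellite genotype container and population-genetic statistics.

Individuals are diploid; each locus call is a pair of integer allele states
(fragment sizes or simulator allele labels), either fully observed or fully
missing.  Every individual is assigned to one network node and one species.

Estimator conventions (recorded in output metadata):

* Expected heterozygosity defaults to the unbiased small-sample estimator
  Hs = n/(n-1) * (1 - sum p_a^2 - Ho/(2n)); the plain gene diversity
  1 - sum p_a^2 is available with ``unbiased=False``.
* Allelic richness is rarefied to a common number of gene copies g by the
  hypergeometric expectation AR_g = sum_a [1 - C(N-N_a, g) / C(N, g)].
* Pairwise F_ST follows Nei (1987): per locus, Hs is the mean unbiased
  within-population gene diversity and Ht the total gene diversity from
  mean allele frequencies with Nei's sample-size corrections; Hs and Ht are
  averaged over loci before the ratio (Ht - Hs)/Ht is taken.  Small negative
  values are estimator artefacts and are reported as computed; zeroing, when
  wanted, is the regression layer's job.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeTable",
    "GenotypeValidationError",
    "read_genotypes",
    "write_genotypes",
    "read_genepop",
    "filter_nodes",
    "subsample",
    "allele_frequencies",
    "allele_counts",
    "allelic_richness",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "fis",
    "node_diversity",
    "pairwise_nei_fst",
    "m_ratio",
    "mantel_test",
]

MISSING = -1  # internal sentinel for a missing locus call


class GenotypeValidationError(ValueError):
    pass


def _locus_columns(columns: Iterable[str]) -> list[str]:
    """Locus base names from paired `<locus>_a1` / `<locus>_a2` columns."""
    a1 = {c[:-3] for c in columns if c.endswith("_a1")}
    a2 = {c[:-3] for c in columns if c.endswith("_a2")}
    loci = sorted(a1 & a2)
    if a1 != a2:
        raise GenotypeValidationError(
            f"unpaired allele columns for loci: {sorted(a1 ^ a2)}"
        )
    return loci


@dataclass
class GenotypeTable:
    """Individuals x loci diploid genotype table.

    ``data`` holds one row per individual with columns ``individual_id``,
    ``node_id``, ``species`` and, per locus, integer columns ``<locus>_a1``
    and ``<locus>_a2`` with missing calls encoded as -1 in both columns.
    """

    data: pd.DataFrame
    loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.loci:
            self.loci = _locus_columns(self.data.columns)
        self.validate()

    def validate(self) -> None:
        df = self.data
        if df["individual_id"].duplicated().any():
            dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
            raise GenotypeValidationError(f"duplicate individual id {dup!r}")
        for loc in self.loci:
            a1 = df[f"{loc}_a1"].to_numpy()
            a2 = df[f"{loc}_a2"].to_numpy()
            half = (a1 == MISSING) ^ (a2 == MISSING)
            if half.any():
                ind = df.loc[half, "individual_id"].iloc[0]
                raise GenotypeValidationError(
                    f"half-missing call at locus {loc} for individual {ind!r}"
                )
            obs = a1 != MISSING
            if (a1[obs] <= 0).any() or (a2[obs] <= 0).any():
                raise GenotypeValidationError(
                    f"non-positive allele state at locus {loc}"
                )

    # -- accessors ---------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.data)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def groups(self) -> pd.core.groupby.DataFrameGroupBy:
        """Group by (node_id, species)."""
        return self.data.groupby(["node_id", "species"], sort=True)

    def sample_sizes(self) -> pd.Series:
        """Individuals per (node, species) group."""
        return self.groups().size()

    def species_list(self) -> list:
        return sorted(self.data["species"].unique())

    def subset_species(self, species) -> "GenotypeTable":
        return GenotypeTable(
            self.data[self.data["species"] == species].reset_index(drop=True),
            loci=self.loci,
        )

    def alleles(self, node_id, species, locus: str) -> np.ndarray:
        """Observed gene copies (2 per observed individual) at one locus."""
        sel = (self.data["node_id"] == node_id) & (self.data["species"] == species)
        a1 = self.data.loc[sel, f"{locus}_a1"].to_numpy()
        a2 = self.data.loc[sel, f"{locus}_a2"].to_numpy()
        copies = np.concatenate([a1, a2])
        return copies[copies != MISSING]


def read_genotypes(path) -> GenotypeTable:
    """Read a genotype TSV.

    Columns ``individual_id``, ``node_id``, ``species`` then paired integer
    allele columns ``<locus>_a1``/``<locus>_a2``; missing calls are encoded
    as empty cells or ``NA``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"node_id": str, "individual_id": str})
    loci = _locus_columns(df.columns)
    for loc in loci:
        for a in ("_a1", "_a2"):
            col = f"{loc}{a}"
            df[col] = (
                pd.to_numeric(df[col], errors="coerce").fillna(MISSING).astype(int)
            )
    return GenotypeTable(df, loci=loci)


def write_genotypes(gt: GenotypeTable, path) -> None:
    df = gt.data.copy()
    for loc in gt.loci:
        for a in ("_a1", "_a2"):
            col = f"{loc}{a}"
            df[col] = df[col].astype("object")
            df.loc[df[col] == MISSING, col] = ""
    df.to_csv(path, sep="\t", index=False)


def read_genepop(path, species: str = "NA") -> GenotypeTable:
    """Import a genepop-format file (2- or 3-digit allele encoding).

    Populations become node ids ``pop1``, ``pop2``, ... unless the last
    individual label of each POP block names the population (the usual
    genepop convention: label before the comma).
    """
    lines = [ln.rstrip("\n") for ln in open(path)]
    # title line, then locus names until first POP
    i = 1
    loci: list[str] = []
    while i < len(lines) and lines[i].strip().lower() != "pop":
        loci.extend([x.strip() for x in lines[i].split(",") if x.strip()])
        i += 1
    rows = []
    pop_idx = 0
    counter = itertools.count(1)
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_idx += 1
            i += 1
            continue
        if not lines[i].strip():
            i += 1
            continue
        label, _, rest = lines[i].partition(",")
        calls = rest.split()
        if len(calls) != len(loci):
            raise GenotypeValidationError(
                f"genepop line with {len(calls)} calls for {len(loci)} loci"
            )
        row = {
            "individual_id": f"ind{next(counter)}",
            "node_id": label.strip() or f"pop{pop_idx}",
            "species": species,
        }
        for loc, call in zip(loci, calls):
            w = len(call) // 2
            a1, a2 = int(call[:w]), int(call[w:])
            if (a1 == 0) != (a2 == 0):
                raise GenotypeValidationError(
                    f"half-missing genepop call {call!r} at locus {loc}"
                )
            row[f"{loc}_a1"] = a1 if a1 else MISSING
            row[f"{loc}_a2"] = a2 if a2 else MISSING
        rows.append(row)
        i += 1
    return GenotypeTable(pd.DataFrame(rows), loci=loci)


def filter_nodes(gt: GenotypeTable, min_n: int = 15) -> GenotypeTable:
    """Keep only (node, species) groups with at least ``min_n`` genotyped
    individuals — the study-inclusion filter for site-level statistics."""
    sizes = gt.sample_sizes()
    keep = sizes[sizes >= min_n].index
    mask = pd.MultiIndex.from_frame(gt.data[["node_id", "species"]]).isin(keep)
    out = gt.data[mask].reset_index(drop=True)
    if out.empty:
        raise GenotypeValidationError(
            f"no (node, species) group has >= {min_n} individuals"
        )
    return GenotypeTable(out, loci=gt.loci)


def subsample(
    gt: GenotypeTable, n_per_group, seed: int | None = None
) -> GenotypeTable:
    """Random subsample of individuals per (node, species) group.

    ``n_per_group`` is an int or a mapping (node_id -> n) / ((node_id,
    species) -> n); groups smaller than the requested size are kept whole.
    Used to match simulated sample sizes to empirical ones before computing
    rarefaction-sensitive statistics.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for key, grp in gt.groups():
        if isinstance(n_per_group, int):
            n = n_per_group
        elif key in n_per_group:
            n = n_per_group[key]
        elif key[0] in n_per_group:
            n = n_per_group[key[0]]
        else:
            n = len(grp)
        if n < len(grp):
            idx = rng.choice(len(grp), size=n, replace=False)
            grp = grp.iloc[np.sort(idx)]
        parts.append(grp)
    return GenotypeTable(
        pd.concat(parts, ignore_index=True), loci=gt.loci
    )


# ---------------------------------------------------------------------------
# Frequencies and per-locus statistics
# ---------------------------------------------------------------------------

def allele_counts(copies: np.ndarray) -> dict[int, int]:
    vals, cnt = np.unique(copies, return_counts=True)
    return dict(zip(vals.tolist(), cnt.tolist()))


def allele_frequencies(gt: GenotypeTable, node_id, species, locus: str) -> dict:
    """Allele relative frequencies over the observed gene copies at a locus."""
    copies = gt.alleles(node_id, species, locus)
    if copies.size == 0:
        raise GenotypeValidationError(
            f"locus {locus} has no observed calls at node {node_id!r}"
        )
    counts = allele_counts(copies)
    n = copies.size
    return {a: c / n for a, c in counts.items()}


def _rarefied_richness(counts: Sequence[int], g: int) -> float:
    """Expected distinct alleles in g gene copies drawn without replacement.

    Uses log-gamma for the hypergeometric absence probability
    C(N - N_a, g) / C(N, g); exact for small N, stable for large.
    """
    counts = np.asarray(list(counts), dtype=float)
    N = counts.sum()
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds gene copies N={int(N)}")
    rem = N - counts
    with np.errstate(invalid="ignore"):
        log_absent = (
            gammaln(rem + 1)
            - gammaln(rem - g + 1)
            - (gammaln(N + 1) - gammaln(N - g + 1))
        )
    p_absent = np.where(rem < g, 0.0, np.exp(log_absent))
    return float(np.sum(1.0 - p_absent))


def allelic_richness(
    gt: GenotypeTable, g: int | None = None
) -> tuple[pd.DataFrame, int]:
    """Rarefied allelic richness per (node, species, locus).

    Parameters
    ----------
    g
        Rarefaction size in gene copies.  Default: twice the smallest number
        of fully observed individuals over all (node, species, locus) cells
        (rarefy-to-minimum convention).  Must be >= 2 and no larger than the
        smallest cell.

    Returns
    -------
    (table, g) where table has one row per (node, species) with per-locus
    AR columns and their mean ``AR``.
    """
    cells: dict[tuple, dict[str, float]] = {}
    min_copies = None
    min_where = None
    for (node, sp), grp in gt.groups():
        for loc in gt.loci:
            copies = grp[f"{loc}_a1"].to_numpy()
            obs = int((copies != MISSING).sum()) * 2
            if obs == 0:
                continue
            if min_copies is None or obs < min_copies:
                min_copies, min_where = obs, (node, sp, loc)
    if min_copies is None:
        raise GenotypeValidationError("no observed calls anywhere")
    if g is None:
        g = min_copies
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    if g > min_copies:
        raise ValueError(
            f"g={g} exceeds the smallest observed cell ({min_copies} gene copies "
            f"at node={min_where[0]!r}, species={min_where[1]!r}, locus={min_where[2]})"
        )
    rows = []
    for (node, sp), grp in gt.groups():
        row: dict = {"node_id": node, "species": sp}
        vals = []
        for loc in gt.loci:
            a1 = grp[f"{loc}_a1"].to_numpy()
            a2 = grp[f"{loc}_a2"].to_numpy()
            copies = np.concatenate([a1, a2])
            copies = copies[copies != MISSING]
            if copies.size == 0:
                row[f"AR_{loc}"] = np.nan
                continue
            ar = _rarefied_richness(list(allele_counts(copies).values()), g)
            row[f"AR_{loc}"] = ar
            vals.append(ar)
        row["AR"] = float(np.mean(vals)) if vals else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index(["node_id", "species"]), g


def observed_heterozygosity(gt: GenotypeTable) -> pd.DataFrame:
    """Fraction of observed individuals heterozygous at each locus, per
    (node, species), plus the across-locus mean ``Ho``."""
    rows = []
    for (node, sp), grp in gt.groups():
        row: dict = {"node_id": node, "species": sp}
        vals = []
        for loc in gt.loci:
            a1 = grp[f"{loc}_a1"].to_numpy()
            a2 = grp[f"{loc}_a2"].to_numpy()
            obs = a1 != MISSING
            if not obs.any():
                row[f"Ho_{loc}"] = np.nan
                continue
            ho = float(np.mean(a1[obs] != a2[obs]))
            row[f"Ho_{loc}"] = ho
            vals.append(ho)
        row["Ho"] = float(np.mean(vals)) if vals else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index(["node_id", "species"])


def _unbiased_hs(a1: np.ndarray, a2: np.ndarray) -> float:
    """Nei's unbiased within-population gene diversity for one locus."""
    obs = a1 != MISSING
    n = int(obs.sum())
    if n < 2:
        raise ValueError("unbiased gene diversity needs >= 2 observed individuals")
    copies = np.concatenate([a1[obs], a2[obs]])
    _, cnt = np.unique(copies, return_counts=True)
    p = cnt / (2 * n)
    ho = float(np.mean(a1[obs] != a2[obs]))
    return n / (n - 1) * (1.0 - float(np.sum(p**2)) - ho / (2 * n))


def expected_heterozygosity(gt: GenotypeTable, unbiased: bool = True) -> pd.DataFrame:
    """Gene diversity per (node, species, locus) and across-locus mean ``He``.

    ``unbiased=True`` (default) applies the small-sample correction
    Hs = n/(n-1) (1 - sum p^2 - Ho/(2n)); otherwise plain 1 - sum p^2.
    """
    rows = []
    for (node, sp), grp in gt.groups():
        row: dict = {"node_id": node, "species": sp}
        vals = []
        for loc in gt.loci:
            a1 = grp[f"{loc}_a1"].to_numpy()
            a2 = grp[f"{loc}_a2"].to_numpy()
            obs = a1 != MISSING
            n = int(obs.sum())
            if n == 0:
                row[f"He_{loc}"] = np.nan
                continue
            if unbiased:
                he = _unbiased_hs(a1, a2)
            else:
                copies = np.concatenate([a1[obs], a2[obs]])
                _, cnt = np.unique(copies, return_counts=True)
                p = cnt / copies.size
                he = 1.0 - float(np.sum(p**2))
            row[f"He_{loc}"] = he
            vals.append(he)
        row["He"] = float(np.mean(vals)) if vals else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index(["node_id", "species"])


def fis(gt: GenotypeTable) -> pd.Series:
    """Inbreeding coefficient F_IS = 1 - mean(Ho)/mean(Hs) per (node,
    species), the ratio of locus means with Hs the unbiased gene diversity."""
    ho = observed_heterozygosity(gt)
    hs = expected_heterozygosity(gt, unbiased=True)
    out = {}
    for key in ho.index:
        ho_m = np.nanmean([ho.loc[key, f"Ho_{loc}"] for loc in gt.loci])
        hs_m = np.nanmean([hs.loc[key, f"He_{loc}"] for loc in gt.loci])
        out[key] = 1.0 - ho_m / hs_m if hs_m > 0 else np.nan
    s = pd.Series(out, name="Fis")
    s.index = pd.MultiIndex.from_tuples(s.index, names=["node_id", "species"])
    return s


def node_diversity(gt: GenotypeTable, g: int | None = None) -> pd.DataFrame:
    """Per-(node, species) summary: n, g, AR, Ho, He, Fis."""
    ar, g_used = allelic_richness(gt, g=g)
    ho = observed_heterozygosity(gt)
    he = expected_heterozygosity(gt, unbiased=True)
    f = fis(gt)
    out = pd.DataFrame(
        {
            "n": gt.sample_sizes(),
            "g": g_used,
            "AR": ar["AR"],
            "Ho": ho["Ho"],
            "He": he["He"],
            "Fis": f,
        }
    )
    return out


# ---------------------------------------------------------------------------
# Pairwise differentiation
# ---------------------------------------------------------------------------

def _pair_fst(
    gt: GenotypeTable, key_a: tuple, key_b: tuple
) -> float:
    """Nei (1987) F_ST for one population pair, loci averaged before ratio."""
    hs_loci, ht_loci = [], []
    for loc in gt.loci:
        stats = []
        for node, sp in (key_a, key_b):
            sel = (gt.data["node_id"] == node) & (gt.data["species"] == sp)
            a1 = gt.data.loc[sel, f"{loc}_a1"].to_numpy()
            a2 = gt.data.loc[sel, f"{loc}_a2"].to_numpy()
            obs = a1 != MISSING
            n = int(obs.sum())
            if n < 2:
                stats = []
                break
            copies = np.concatenate([a1[obs], a2[obs]])
            vals, cnt = np.unique(copies, return_counts=True)
            p = dict(zip(vals.tolist(), (cnt / (2 * n)).tolist()))
            ho = float(np.mean(a1[obs] != a2[obs]))
            stats.append((n, p, ho))
        if not stats:
            continue  # locus observed in only one of the two populations
        ns = np.array([s[0] for s in stats], dtype=float)
        n_harm = len(stats) / np.sum(1.0 / ns)
        ho_bar = float(np.mean([s[2] for s in stats]))
        sum_p2 = float(np.mean([sum(v * v for v in s[1].values()) for s in stats]))
        hs = n_harm / (n_harm - 1) * (1.0 - sum_p2 - ho_bar / (2 * n_harm))
        alleles = set().union(*(s[1].keys() for s in stats))
        pbar2 = sum(
            (np.mean([s[1].get(a, 0.0) for s in stats])) ** 2 for a in alleles
        )
        npop = len(stats)
        ht = (
            1.0
            - float(pbar2)
            + hs / (n_harm * npop)
            - ho_bar / (2 * n_harm * npop)
        )
        hs_loci.append(hs)
        ht_loci.append(ht)
    if not ht_loci:
        return np.nan
    hs_m, ht_m = float(np.mean(hs_loci)), float(np.mean(ht_loci))
    if ht_m <= 0:
        return np.nan  # no diversity anywhere: differentiation undefined
    return (ht_m - hs_m) / ht_m


def pairwise_nei_fst(gt: GenotypeTable, species=None) -> pd.DataFrame:
    """Symmetric matrix of pairwise Nei F_ST between nodes.

    If ``species`` is given, only that species' nodes enter; otherwise the
    table must contain a single species.  Undefined pairs (no shared
    polymorphic locus) are NaN.
    """
    if species is not None:
        gt = gt.subset_species(species)
    sps = gt.species_list()
    if len(sps) != 1:
        raise GenotypeValidationError(
            "pairwise F_ST needs a single species; pass species=..."
        )
    sp = sps[0]
    nodes = sorted(gt.data["node_id"].unique())
    k = len(nodes)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            v = _pair_fst(gt, (nodes[i], sp), (nodes[j], sp))
            mat[i, j] = mat[j, i] = v
    return pd.DataFrame(mat, index=nodes, columns=nodes)


def fst_long(fst: pd.DataFrame) -> pd.DataFrame:
    """Upper-triangle long format: node_a, node_b, fst."""
    rows = []
    nodes = list(fst.index)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            rows.append({"node_a": a, "node_b": b, "fst": fst.loc[a, b]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bottleneck statistic and matrix correlation
# ---------------------------------------------------------------------------

def m_ratio(gt: GenotypeTable) -> pd.DataFrame:
    """Garza-Williamson M = k / (r + 1) per (node, species, locus): number of
    distinct allele sizes over the allele-size range plus one (1-unit repeat
    ladder assumed).  Monomorphic loci give M = 1 by convention."""
    rows = []
    for (node, sp), grp in gt.groups():
        row: dict = {"node_id": node, "species": sp}
        vals = []
        for loc in gt.loci:
            a1 = grp[f"{loc}_a1"].to_numpy()
            a2 = grp[f"{loc}_a2"].to_numpy()
            copies = np.concatenate([a1, a2])
            copies = copies[copies != MISSING]
            if copies.size == 0:
                row[f"M_{loc}"] = np.nan
                continue
            k = len(np.unique(copies))
            r = int(copies.max() - copies.min())
            m = k / (r + 1)
            row[f"M_{loc}"] = m
            vals.append(m)
        row["M"] = float(np.mean(vals)) if vals else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index(["node_id", "species"])


def mantel_test(
    m1, m2, n_perm: int = 1000, seed: int | None = None
) -> tuple[float, float]:
    """Mantel test between two symmetric matrices in identical node order.

    Returns (r, p): r is the Pearson correlation of the upper-triangle
    entries; p is the one-tailed permutation p-value for positive
    association, computed by jointly permuting rows and columns of the
    second matrix, with add-one smoothing (b + 1)/(n_perm + 1).
    """
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of identical shape")
    iu = np.triu_indices(a.shape[0], k=1)
    va = a[iu]
    if np.std(va) == 0 or np.std(b[iu]) == 0:
        raise ValueError("zero-variance matrix: Mantel r undefined")

    def corr(mat_b):
        vb = mat_b[iu]
        return float(np.corrcoef(va, vb)[0, 1])

    r_obs = corr(b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(a.shape[0])
        if corr(b[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, p
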