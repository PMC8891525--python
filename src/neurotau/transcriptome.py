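"""Gene-expression association with a difference map and gene-set enrichment.

Genes are ranked by the Pearson correlation between their parcel-level
expression profile and the parcel-aggregated unthresholded t-map, restricted
to left-hemisphere parcels by default (donor coverage of expression atlases
is left-dominant).  A gene enters the positive (negative) list when
r > +r_thresh (r < -r_thresh) and its Bonferroni-corrected p is below alpha.

Enrichment of a gene list against a GMT collection uses the one-sided
hypergeometric tail P[X >= k] with Benjamini-Hochberg FDR across terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, InsufficientDataError, SchemaError
from .spatial_assoc import ParcelProfile

log = logging.getLogger("neurotau")

MIN_PARCELS_PER_GENE = 10


# ---------------------------------------------------------------------------
# Containers


@dataclass
class ExpressionMatrix:
    """Gene x parcel expression with per-parcel hemisphere tags."""

    values: pd.DataFrame  # index: gene symbols, columns: parcel ids
    hemisphere: pd.Series  # index: parcel ids -> {left, right, midline}

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise SchemaError(f"duplicate gene symbols: {dup[:5]}")
        missing = [c for c in self.values.columns if c not in self.hemisphere.index]
        if missing:
            raise SchemaError(f"parcels without hemisphere tag: {missing[:5]}")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    def parcels(self, hemisphere: str = "both") -> np.ndarray:
        cols = np.asarray(self.values.columns)
        if hemisphere == "both":
            return cols
        tags = self.hemisphere.loc[cols].to_numpy()
        return cols[tags == hemisphere]


@dataclass
class GeneSetCollection:
    terms: dict[str, frozenset]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        empty = [t for t, g in self.terms.items() if not g]
        if empty:
            raise DataError(f"empty gene sets: {empty[:5]}")


def read_gmt(path) -> GeneSetCollection:
    terms, descriptions = {}, {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, desc, *genes = parts
            terms[name] = frozenset(g for g in genes if g)
            descriptions[name] = desc
    if not terms:
        raise SchemaError(f"no gene sets parsed from {path}")
    return GeneSetCollection(terms=terms, descriptions=descriptions)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.terms.items():
            desc = sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_expression(expr_path, parcel_meta_path) -> ExpressionMatrix:
    """Expression TSV (first column gene symbol) + parcel metadata TSV
    (columns parcel_id, hemisphere)."""
    frame = pd.read_csv(expr_path, sep="\t")
    frame = frame.set_index(frame.columns[0])
    frame.columns = frame.columns.astype(int)
    meta = pd.read_csv(parcel_meta_path, sep="\t")
    if not {"parcel_id", "hemisphere"} <= set(meta.columns):
        raise SchemaError("parcel metadata needs parcel_id and hemisphere columns")
    hemi = meta.set_index("parcel_id")["hemisphere"]
    return ExpressionMatrix(values=frame, hemisphere=hemi)


# ---------------------------------------------------------------------------
# Gene ranking


def rank_genes(
    expr: ExpressionMatrix,
    target: ParcelProfile,
    hemisphere: str = "left",
    r_thresh: float = 0.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate each gene's expression profile with the target profile.

    Returns a DataFrame indexed by gene with columns r, p, p_fwe (Bonferroni
    over the genes actually tested), n_parcels, and list in
    {positive, negative, none, excluded}.
    """
    if hemisphere not in ("left", "both"):
        raise DataError(f"hemisphere must be 'left' or 'both', got {hemisphere!r}")
    tgt = target.series()
    parcels = [p for p in expr.parcels(hemisphere) if p in tgt.index]
    tvals = tgt.loc[parcels].to_numpy(dtype=float)
    keep = ~np.isnan(tvals)
    parcels = np.asarray(parcels)[keep]
    tvals = tvals[keep]
    if parcels.size < MIN_PARCELS_PER_GENE:
        raise InsufficientDataError(
            f"only {parcels.size} parcels shared with the target"
        )
    E = expr.values[list(parcels)].to_numpy(dtype=float)

    genes = np.asarray(expr.genes)
    r = np.full(genes.size, np.nan)
    n_eff = np.zeros(genes.size, dtype=int)
    for i in range(genes.size):
        e = E[i]
        okg = ~np.isnan(e)
        n = int(okg.sum())
        n_eff[i] = n
        if n < MIN_PARCELS_PER_GENE:
            continue
        ev, tv = e[okg], tvals[okg]
        if np.ptp(ev) == 0 or np.ptp(tv) == 0:
            continue
        r[i] = np.corrcoef(ev, tv)[0, 1]

    tested = ~np.isnan(r)
    n_tested = int(tested.sum())
    if n_tested == 0:
        raise InsufficientDataError("no testable genes")
    log.info("rank_genes: %d/%d genes tested (Bonferroni family size %d)",
             n_tested, genes.size, n_tested)
    p = np.full(genes.size, np.nan)
    df = n_eff[tested] - 2
    rt = np.clip(r[tested], -1 + 1e-15, 1 - 1e-15)
    tstat = rt * np.sqrt(df / (1 - rt**2))
    p[tested] = 2 * stats.t.sf(np.abs(tstat), df)
    p_fwe = np.minimum(p * n_tested, 1.0)

    lists = np.full(genes.size, "none", dtype=object)
    lists[~tested] = "excluded"
    sig = tested & (p_fwe < alpha)
    lists[sig & (r > r_thresh)] = "positive"
    lists[sig & (r < -r_thresh)] = "negative"

    return pd.DataFrame(
        {"r": r, "p": p, "p_fwe": p_fwe, "n_parcels": n_eff, "list": lists},
        index=pd.Index(genes, name="gene"),
    )


# ---------------------------------------------------------------------------
# Hypergeometric enrichment


def hypergeometric_enrichment(
    gene_list,
    sets: GeneSetCollection,
    universe,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment with BH-FDR across terms.

    For a term with K members in the universe of size N and a list of size n
    with overlap k, p = P[X >= k], X ~ Hypergeometric(N, K, n).
    """
    universe = frozenset(universe)
    gene_list = frozenset(gene_list)
    if not gene_list or not universe:
        raise DataError("gene list and universe must be non-empty")
    if not gene_list <= universe:
        extra = sorted(gene_list - universe)
        raise DataError(f"gene list not contained in universe: {extra[:5]}")
    N, n = len(universe), len(gene_list)
    rows = []
    for name, members in sets.terms.items():
        term = members & universe
        K = len(term)
        if K == 0:
            continue
        k = len(term & gene_list)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, p))
    if not rows:
        raise DataError("no gene set overlaps the universe")
    frame = pd.DataFrame(
        rows, columns=["term", "k", "K", "n", "N", "p_hyper"]
    ).set_index("term")
    frame["q_fdr"] = multipletests(frame["p_hyper"].to_numpy(), method="fdr_bh")[1]
    frame["significant"] = frame["q_fdr"] < q_threshold
    frame["description"] = [sets.descriptions.get(t, "") for t in frame.index]
    return frame.sort_values(["q_fdr", "p_hyper"])


def shared_terms(
    a: pd.DataFrame, b: pd.DataFrame, q_threshold: float = 0.05
) -> list[str]:
    """Terms significant (q < threshold) in both enrichment results,
    sorted by the larger of the two q values."""
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise DataError("enrichment results share no terms")
    sig = [
        t
        for t in common
        if a.loc[t, "q_fdr"] < q_threshold and b.loc[t, "q_fdr"] < q_threshold
    ]
    return sorted(sig, key=lambda t: max(a.loc[t, "q_fdr"], b.loc[t, "q_fdr"]))
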