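"""Metagene signature definitions, probe collapsing, scoring and tertiles.

A metagene is a cluster of coordinately expressed genes summarized per
tumor as a single score: probe sets mapping to the same gene are averaged
first, then the gene-level values are averaged across the member genes.
Four metagenes are modeled: three immune ones — B/P (B cells / plasma
cells), T/NK (T and natural-killer cells), M/D (monocytes / dendritic
cells) — and a proliferation metagene P. Samples are stratified into
low / intermediate / high tertiles of a score where needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

__all__ = [
    "METAGENES",
    "DEFAULT_EXCLUSION_PROBES",
    "SignatureSet",
    "load_signatures",
    "collapse_probes",
    "score_metagene",
    "score_all_metagenes",
    "mean_center",
    "assign_tertiles",
    "load_md_gene_annotation",
    "count_mhc_class_ii",
]

log = logging.getLogger(__name__)

METAGENES = ("B/P", "T/NK", "M/D", "P")

#: Probe sets shared between the T/NK and M/D definitions, removed by
#: default so the two immune compartments stay disjoint.
DEFAULT_EXCLUSION_PROBES = ("200904_at", "204834_at", "211742_s_at")


class SignatureFormatError(ValueError):
    pass


class CoverageError(ValueError):
    """Too few signature probes present in the expression matrix."""


@dataclass
class SignatureSet:
    """Validated metagene membership table.

    ``entries`` has columns probe_id, gene_symbol, metagene; after the
    exclusion list is applied no probe may belong to more than one
    metagene and every metagene keeps at least one probe.
    """

    entries: pd.DataFrame
    exclusion_list: tuple[str, ...] = field(default=DEFAULT_EXCLUSION_PROBES)
    n_excluded: int = 0

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_symbol", "metagene"}
        if not required <= set(self.entries.columns):
            raise SignatureFormatError(f"signature table needs columns {sorted(required)}")
        unknown = set(self.entries["metagene"]) - set(METAGENES)
        if unknown:
            raise SignatureFormatError(f"unknown metagene name(s): {sorted(unknown)}")
        dup = self.entries.groupby("probe_id")["metagene"].nunique()
        shared = dup.index[dup > 1].tolist()
        if shared:
            raise SignatureFormatError(
                f"probe(s) assigned to more than one metagene after exclusion: {shared[:5]}")
        present = set(self.entries["metagene"])
        missing = [m for m in METAGENES if m in present and
                   self.entries.loc[self.entries["metagene"] == m].empty]
        if missing:
            raise SignatureFormatError(f"metagene(s) left without probes: {missing}")

    def probes(self, metagene: str) -> pd.DataFrame:
        if metagene not in METAGENES:
            raise SignatureFormatError(f"unknown metagene {metagene!r}")
        return self.entries.loc[self.entries["metagene"] == metagene]

    def counts(self) -> pd.DataFrame:
        """Probe and gene counts per metagene (after exclusion)."""
        g = self.entries.groupby("metagene")
        return pd.DataFrame({"n_probes": g["probe_id"].nunique(),
                             "n_genes": g["gene_symbol"].nunique()})


def load_signatures(path: str | Path,
                    exclusion_list: tuple[str, ...] = DEFAULT_EXCLUSION_PROBES
                    ) -> SignatureSet:
    """Load a signature TSV (columns probe_id, gene_symbol, metagene).

    Rows whose probe is on the exclusion list are dropped and counted;
    probe/gene counts before and after exclusion are logged, since
    published signature sizes may be quoted on either convention.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.empty:
        raise SignatureFormatError(f"empty signature file: {path}")
    before = len(table)
    table = table.loc[~table["probe_id"].isin(set(exclusion_list))].reset_index(drop=True)
    n_excluded = before - len(table)
    if n_excluded:
        log.info("load_signatures: %d probe row(s) dropped by exclusion list "
                 "(%d before, %d after)", n_excluded, before, len(table))
    if table.empty:
        raise SignatureFormatError("no signature rows remain after exclusion")
    return SignatureSet(table, tuple(exclusion_list), n_excluded)


def collapse_probes(matrix: ExpressionMatrix, sig: SignatureSet, metagene: str,
                    min_coverage: float = 0.5) -> pd.DataFrame:
    """Collapse a metagene's probe rows to a gene-by-sample matrix.

    Probes mapping to the same gene symbol are averaged. Signature probes
    absent from the matrix are skipped and logged; if fewer than
    ``min_coverage`` of the metagene's probes are present a
    :class:`CoverageError` is raised, because the upstream pipeline is
    expected to work on a common probe panel where near-full coverage is
    the norm.
    """
    members = sig.probes(metagene)
    present = members["probe_id"].isin(matrix.values.index)
    if present.sum() == 0 or present.mean() < min_coverage:
        raise CoverageError(
            f"{metagene}: only {int(present.sum())}/{len(members)} signature probes "
            "present in the matrix")
    if (~present).any():
        log.info("collapse_probes %s: %d probe(s) absent from matrix, skipped",
                 metagene, int((~present).sum()))
    members = members.loc[present]
    sub = matrix.values.loc[members["probe_id"]]
    sub.index = members["gene_symbol"].to_numpy()
    return sub.groupby(level=0, sort=True).mean()


def score_metagene(gene_matrix: pd.DataFrame) -> pd.Series:
    """Average gene-level values into one score per sample.

    Sample columns with no measured gene at all come back as NaN.
    """
    if gene_matrix.empty:
        raise CoverageError("empty gene-level matrix")
    return gene_matrix.mean(axis=0, skipna=True)


def score_all_metagenes(matrix: ExpressionMatrix, sig: SignatureSet,
                        metagenes: tuple[str, ...] = METAGENES) -> pd.DataFrame:
    """Samples-by-metagenes score table (uncentered log2 averages)."""
    cols = {}
    for m in metagenes:
        if not sig.probes(m).empty:
            cols[m] = score_metagene(collapse_probes(matrix, sig, m))
    return pd.DataFrame(cols)


def mean_center(scores: pd.Series) -> pd.Series:
    """Subtract the mean of the finite scores (rank order preserved).

    Used for cross-dataset distribution comparison only; modeling uses
    the raw uncentered averages.
    """
    finite = scores.dropna()
    if finite.empty:
        raise ValueError("no finite scores to center")
    return scores - finite.mean()


def assign_tertiles(scores: pd.Series) -> pd.Series:
    """Label samples low / intermediate / high by score tertile.

    Thresholds are the empirical 33rd/66th percentiles taken at the lower
    adjacent order statistic; a score equal to a threshold falls in the
    lower group. This yields the identical partition to linear-
    interpolated thresholds under the ``<=`` rule (any cut strictly
    between consecutive order statistics groups the same samples) while
    staying exactly invariant under monotone transforms of the scores.
    Degenerate distributions (massive ties) may leave a group empty,
    which is reported as a warning rather than an error.
    """
    finite = scores.dropna()
    if len(finite) < 3:
        raise ValueError("tertile assignment requires at least 3 finite scores")
    lo, hi = np.percentile(finite.to_numpy(), [100 / 3, 200 / 3], method="lower")
    labels = pd.Series(pd.NA, index=scores.index, dtype="object")
    labels[scores <= lo] = "low"
    labels[(scores > lo) & (scores <= hi)] = "intermediate"
    labels[scores > hi] = "high"
    counts = labels.value_counts()
    if any(counts.get(g, 0) == 0 for g in ("low", "intermediate", "high")):
        log.warning("assign_tertiles: degenerate score distribution, group sizes %s",
                    counts.to_dict())
    return labels


# ---------------------------------------------------------------------------
# Packaged M/D membership fixture

_MD_FIXTURE = "md_metagene_genes_synthetic.tsv"


def load_md_gene_annotation() -> pd.DataFrame:
    """Load the packaged M/D metagene gene list (19 genes).

    The monocyte/dendritic-cell metagene members that are individually
    documented — the nine MHC class II antigen-presentation genes and
    CSF1R — carry their real symbols; the remaining members are synthetic
    stand-in symbols, since the full published list is not bundled.
    """
    with resources.files("immunomet.data").joinpath(_MD_FIXTURE).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def count_mhc_class_ii(gene_symbols) -> int:
    """Count genes in MHC class II-mediated antigen presentation.

    Membership is determined from the symbol itself: classical and
    non-classical class II loci (HLA-D*) plus the invariant chain CD74.
    """
    syms = pd.Series(list(gene_symbols), dtype=str)
    return int((syms.str.startswith("HLA-D") | (syms == "CD74")).sum())


def spearman_rank_preserved(before: pd.Series, after: pd.Series) -> float:
    """Spearman correlation between two score vectors (audit helper)."""
    rho, _ = stats.spearmanr(before, after)
    return float(rho)
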