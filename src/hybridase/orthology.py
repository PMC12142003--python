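"""One-to-one ortholog pairing and one-to-n homolog grouping.

One-to-one pairs come from reciprocal (mutual) best protein-alignment hits
between the two species; one-to-n groups assign every gene to the reference
term (e.g. a human nuclear-encoded mitochondrial gene) of its single best
hit, so a term may collect many homologs whose expression is later summed.
"""

from __future__ import annotations

import pandas as pd

HIT_COLUMNS = ["query", "subject", "score", "e_value", "qlen", "slen"]

DEFAULT_E_CUTOFF = 1e-4


def read_hits(path) -> pd.DataFrame:
    """Read a 6-column tabular alignment hit table (no header)."""
    return pd.read_csv(path, sep="\t", names=HIT_COLUMNS, header=None)


def select_representatives(models: pd.DataFrame) -> pd.DataFrame:
    """Collapse overlapping gene models to the longest gene and isoform.

    Among genes whose intervals overlap on the same chromosome, only the one
    with the longest genomic span is kept (ties broken by lexicographically
    smaller ``gene_id``); the kept gene is represented by its longest
    protein isoform (same tie-break on ``isoform_id``).

    Parameters
    ----------
    models : pandas.DataFrame
        One row per isoform: ``gene_id``, ``chromosome``, ``start``, ``end``,
        ``isoform_id``, ``protein_length``.

    Returns
    -------
    pandas.DataFrame
        One row per kept gene: ``gene_id``, ``chromosome``, ``start``,
        ``end``, ``isoform_id``, ``protein_length``.
    """
    required = {"gene_id", "chromosome", "start", "end", "isoform_id",
                "protein_length"}
    missing = required - set(models.columns)
    if missing:
        raise ValueError(f"gene models missing columns: {sorted(missing)}")
    if models[["start", "end"]].isna().any().any():
        raise ValueError("gene models with missing coordinates")

    genes = (
        models.groupby("gene_id")
        .agg(
            chromosome=("chromosome", "first"),
            start=("start", "min"),
            end=("end", "max"),
        )
        .reset_index()
    )
    genes["span"] = genes["end"] - genes["start"]

    kept_ids: list[str] = []
    for _, chrom_genes in genes.groupby("chromosome", sort=True):
        ordered = chrom_genes.sort_values(["start", "end", "gene_id"])
        # sweep: maintain the current overlap cluster and its best gene
        cluster_end = None
        best = None
        for row in ordered.itertuples():
            if cluster_end is None or row.start > cluster_end:
                if best is not None:
                    kept_ids.append(best.gene_id)
                best = row
                cluster_end = row.end
            else:
                cluster_end = max(cluster_end, row.end)
                if row.span > best.span or (
                    row.span == best.span and row.gene_id < best.gene_id
                ):
                    best = row
        if best is not None:
            kept_ids.append(best.gene_id)

    iso = models[models["gene_id"].isin(kept_ids)].sort_values(
        ["gene_id", "protein_length", "isoform_id"],
        ascending=[True, False, True],
    )
    reps = iso.groupby("gene_id", as_index=False).first()
    spans = genes.set_index("gene_id")
    reps["start"] = reps["gene_id"].map(spans["start"])
    reps["end"] = reps["gene_id"].map(spans["end"])
    return reps[
        ["gene_id", "chromosome", "start", "end", "isoform_id", "protein_length"]
    ].sort_values("gene_id", ignore_index=True)


def _unique_best(hits: pd.DataFrame) -> dict[str, str]:
    """Best subject per query by score; queries with a tied top score drop."""
    best: dict[str, str] = {}
    for query, sub in hits.groupby("query"):
        top = sub["score"].max()
        winners = sub.loc[sub["score"] == top, "subject"].unique()
        if len(winners) == 1:
            best[query] = winners[0]
    return best


def reciprocal_best_hits(
    forward: pd.DataFrame,
    reverse: pd.DataFrame,
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> pd.DataFrame:
    """One-to-one ortholog pairs from mutual best hits.

    A pair ``(a, b)`` is emitted iff ``b`` is ``a``'s unique top-scoring
    subject in the forward table and ``a`` is ``b``'s unique top-scoring
    subject in the reverse table, after filtering both tables to
    ``e_value < e_cutoff``.  Genes whose top score is tied are excluded.
    Each gene appears in at most one pair.
    """
    fwd = forward[forward["e_value"] < e_cutoff]
    rev = reverse[reverse["e_value"] < e_cutoff]
    if fwd.empty or rev.empty:
        return pd.DataFrame(columns=["query", "subject"])
    best_fwd = _unique_best(fwd)
    best_rev = _unique_best(rev)
    pairs = [
        (a, b)
        for a, b in sorted(best_fwd.items())
        if best_rev.get(b) == a
    ]
    return pd.DataFrame(pairs, columns=["query", "subject"])


def group_one_to_n(
    hits: pd.DataFrame, e_cutoff: float = DEFAULT_E_CUTOFF
) -> dict[str, list[str]]:
    """Assign every gene to the reference term of its best hit.

    Ties on score break by lower e-value, then by lexicographic term id.
    Returns a mapping term -> sorted member gene list; each gene belongs to
    exactly one term.
    """
    kept = hits[hits["e_value"] < e_cutoff]
    groups: dict[str, list[str]] = {}
    for query, sub in kept.groupby("query"):
        ordered = sub.sort_values(
            ["score", "e_value", "subject"], ascending=[False, True, True]
        )
        term = ordered.iloc[0]["subject"]
        groups.setdefault(term, []).append(query)
    return {term: sorted(members) for term, members in sorted(groups.items())}
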