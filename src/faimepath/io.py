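"""Readers and writers for the tabular formats the pipeline touches.

All files are plain TSV (tab-separated, UTF-8, no quoting) or standard GMT.
Gene identity is the symbol string, case-sensitive; no alias resolution is
attempted.  Reading never silently drops a sample or a gene, with one
documented exception: gene tokens in a GMT file that do not look like
official gene symbols (by default, purely numeric identifiers) are removed,
and the number of removed tokens is logged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = ("HC", "PreSSc")
VALID_OUTCOMES = ("stable", "evolving", "none")
VALID_TIMEPOINTS = ("baseline", "followup")

#: Default test for an "official" gene symbol: must start with a letter,
#: then letters/digits/dot/hyphen.  Purely numeric tokens (bare Entrez IDs)
#: fail this test and are dropped at GMT read time.
OFFICIAL_SYMBOL_RE = re.compile(r"^[A-Za-z][A-Za-z0-9.-]*$")

METADATA_COLUMNS = ("sample_id", "subject_id", "group", "outcome", "timepoint")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


@dataclass
class CountMatrix:
    """Raw gene-level counts plus per-sample metadata.

    Parameters
    ----------
    counts : DataFrame
        Genes (rows, unique symbols) by samples (columns, unique ids);
        nonnegative integers.
    metadata : DataFrame
        Indexed by sample id; columns ``subject_id``, ``group`` (HC/PreSSc),
        ``outcome`` (stable/evolving/none), ``timepoint`` (baseline/followup)
        plus any additional covariate columns.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dupes[:5]}")
        if c.columns.duplicated().any():
            dupes = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(arr != np.round(arr))[0]
                raise ValueError(
                    "non-integer count at gene "
                    f"{c.index[bad[0]]!r}, sample {c.columns[bad[1]]!r}"
                )
            self.counts = c = c.astype(np.int64)
            arr = c.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {c.index[bad[0]]!r}, "
                f"sample {c.columns[bad[1]]!r}"
            )
        md = self.metadata
        missing = [s for s in c.columns if s not in md.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        for col in ("subject_id", "group", "outcome", "timepoint"):
            if col not in md.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        bad_group = set(md["group"]) - set(VALID_GROUPS)
        if bad_group:
            raise ValueError(f"unknown group labels: {sorted(bad_group)}")
        bad_out = set(md["outcome"]) - set(VALID_OUTCOMES)
        if bad_out:
            raise ValueError(f"unknown outcome labels: {sorted(bad_out)}")
        bad_tp = set(md["timepoint"]) - set(VALID_TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoint labels: {sorted(bad_tp)}")
        hc_bad = md[(md["group"] == "HC") & (md["outcome"] != "none")]
        if len(hc_bad):
            raise ValueError(
                "HC samples must have outcome 'none': "
                f"{hc_bad.index.tolist()}"
            )
        sub = md.loc[list(c.columns)]
        base_subjects = set(sub.loc[sub["timepoint"] == "baseline", "subject_id"])
        fup = sub[sub["timepoint"] == "followup"]
        orphans = fup.loc[~fup["subject_id"].isin(base_subjects)].index.tolist()
        if orphans:
            raise ValueError(
                f"followup samples without a baseline sample: {orphans}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.metadata)


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional child->parent hierarchy.

    ``sets`` maps pathway id to ``(display name, tuple of unique gene
    symbols)``.  ``hierarchy`` maps a pathway id to its parent id; ids
    absent from the hierarchy are their own roots.
    """

    sets: dict[str, tuple[str, tuple[str, ...]]]
    hierarchy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {pid!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {pid!r} has duplicate genes")
        unknown = [k for k in self.hierarchy if k not in self.sets]
        if unknown:
            raise ValueError(f"hierarchy keys not in collection: {unknown[:5]}")
        _check_acyclic(self.hierarchy)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def genes_of(self, pathway_id: str) -> tuple[str, ...]:
        return self.sets[pathway_id][1]

    def name_of(self, pathway_id: str) -> str:
        return self.sets[pathway_id][0]


def _check_acyclic(parent_of: dict[str, str]) -> None:
    for start in parent_of:
        seen = {start}
        node = start
        while node in parent_of:
            node = parent_of[node]
            if node in seen:
                cycle = [node]
                cur = parent_of[node]
                while cur != node:
                    cycle.append(cur)
                    cur = parent_of[cur]
                raise ValueError(
                    "hierarchy contains a cycle: "
                    + " -> ".join(cycle + [cycle[0]])
                )
            seen.add(node)


def read_gene_sets(
    path,
    symbol_pattern: re.Pattern | str = OFFICIAL_SYMBOL_RE,
) -> GeneSetCollection:
    """Read a GMT file (id, description, gene symbols...).

    Duplicate genes within a set are de-duplicated preserving order.
    Tokens that do not match *symbol_pattern* (identifiers without an
    official gene symbol, e.g. bare Entrez numbers) are dropped and the
    total drop count is logged.
    """
    if isinstance(symbol_pattern, str):
        symbol_pattern = re.compile(symbol_pattern)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    n_dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            pid, desc, *genes = fields
            if pid in sets:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate pathway id {pid!r}"
                )
            kept: list[str] = []
            seen: set[str] = set()
            for g in genes:
                if not g:
                    continue
                if not symbol_pattern.match(g):
                    n_dropped += 1
                    continue
                if g not in seen:
                    seen.add(g)
                    kept.append(g)
            if not kept:
                raise FormatError(
                    f"{path}: line {lineno}: gene set {pid!r} has no valid "
                    "gene symbols"
                )
            sets[pid] = (desc, tuple(kept))
    if n_dropped:
        logger.info("read_gene_sets: dropped %d non-symbol tokens", n_dropped)
    return GeneSetCollection(sets=sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, (desc, genes) in collection.sets.items():
            fh.write("\t".join([pid, desc, *genes]) + "\n")


def read_count_matrix(counts_path, metadata_path) -> CountMatrix:
    """Read a counts TSV (first column gene symbols, header sample ids)
    and a metadata TSV (columns sample_id, subject_id, group, outcome,
    timepoint, plus optional covariates)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    md = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing_cols:
        raise FormatError(
            f"{metadata_path}: missing metadata columns {missing_cols}"
        )
    md = md.set_index("sample_id")
    return CountMatrix(counts=counts, metadata=md)


def write_count_matrix(cm: CountMatrix, counts_path, metadata_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    cm.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_hierarchy(path) -> dict[str, str]:
    """Read a two-column child_id<TAB>parent_id file into an acyclic map."""
    parent_of: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated "
                    f"columns, got {len(fields)}"
                )
            child, parent = fields
            if lineno == 1 and (child, parent) == ("child_id", "parent_id"):
                continue  # optional header
            parent_of[child] = parent
    _check_acyclic(parent_of)
    return parent_of


def write_hierarchy(parent_of: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for child, parent in parent_of.items():
            fh.write(f"{child}\t{parent}\n")
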