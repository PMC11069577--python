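"""MeSH-style hierarchy rollup for condition annotations.

A hierarchy is a table of terms, each carrying one or more dotted tree
numbers (``C10``, ``C10.228``, ``C10.228.140`` ... ).  A term's level is the
minimum depth over its tree numbers; top-level terms have depth 1.  The
reserved pseudo-term "Not found" collects conditions with no good single
heading and is treated as its own top-level heading.

Variants carry condition strings; an externally curated mapping table sends
each condition to a term (or "Not found"; a non-empty qualifier column also
demotes a mapping to "Not found").  Rollup takes each variant's conditions
to the set of top-level headings reachable from their terms and tallies each
heading at most once per variant.

Third-level terms (grandchildren of top-level terms) proxy individual
diseases: a third-level term counts as covered by editing if any predicted
editing site maps to it or to any of its descendants, and as covered by a
C>U SNP only if C>U variants (but no predicted site) map there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

__all__ = ["MeshHierarchy", "load_hierarchy", "load_mapping",
           "count_headings", "third_level_coverage", "NOT_FOUND",
           "HierarchyError"]

logger = logging.getLogger(__name__)

NOT_FOUND = "Not found"


class HierarchyError(ValueError):
    """Orphan or malformed tree numbers."""


@dataclass(frozen=True)
class MeshHierarchy:
    """Validated term table with tree-number indexes."""

    names: dict[str, str]                     # term id -> display name
    tree_numbers: dict[str, tuple[str, ...]]  # term id -> dotted paths
    term_at: dict[str, str]                   # tree number -> term id

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.tree_numbers or term_id == NOT_FOUND

    def level(self, term_id: str) -> int:
        """Minimum tree-number depth (1 = top level)."""
        if term_id == NOT_FOUND:
            return 1
        return min(tn.count(".") + 1 for tn in self.tree_numbers[term_id])

    def ancestors_to_top(self, term_id: str) -> frozenset[str]:
        """Top-level term ids reachable from any of the term's tree numbers;
        "Not found" maps to itself."""
        if term_id == NOT_FOUND:
            return frozenset({NOT_FOUND})
        if term_id not in self.tree_numbers:
            raise KeyError(f"unknown term {term_id!r}")
        tops = set()
        for tn in self.tree_numbers[term_id]:
            root = tn.split(".", 1)[0]
            tops.add(self.term_at[root])
        return frozenset(tops)

    def descendant_tree_numbers(self, tn: str) -> list[str]:
        prefix = tn + "."
        return [t for t in self.term_at if t == tn or t.startswith(prefix)]


def load_hierarchy(table: pd.DataFrame | str) -> MeshHierarchy:
    """Build and validate a hierarchy from a TSV/DataFrame of
    ``term_id, name, tree_numbers`` (semicolon-separated paths).

    Every non-top tree number must have its parent prefix present somewhere
    in the table; orphans raise :class:`HierarchyError`.
    """
    df = (pd.read_csv(table, sep="\t", dtype=str)
          if not isinstance(table, pd.DataFrame) else table)
    names: dict[str, str] = {}
    trees: dict[str, tuple[str, ...]] = {}
    term_at: dict[str, str] = {}
    for term_id, name, tree_field in zip(df["term_id"], df["name"],
                                         df["tree_numbers"]):
        tns = tuple(t.strip() for t in str(tree_field).split(";") if t.strip())
        if not tns:
            raise HierarchyError(f"term {term_id} has no tree numbers")
        names[term_id] = name
        trees[term_id] = tns
        for tn in tns:
            if tn in term_at:
                raise HierarchyError(f"tree number {tn} assigned twice")
            term_at[tn] = term_id
    for tn in term_at:
        if "." in tn:
            parent = tn.rsplit(".", 1)[0]
            if parent not in term_at:
                raise HierarchyError(f"orphan tree number {tn}: parent "
                                     f"{parent} is missing")
    return MeshHierarchy(names=names, tree_numbers=trees, term_at=term_at)


def load_mapping(table: pd.DataFrame | str) -> dict[str, str]:
    """Condition -> term-id mapping.

    Rows with a non-empty ``qualifier`` column are demoted to "Not found"
    (the qualifier marks the supplemental mapping as not a true child of the
    mapped term).
    """
    df = (pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
          if not isinstance(table, pd.DataFrame) else table.fillna(""))
    out: dict[str, str] = {}
    for row in df.itertuples(index=False):
        qualifier = getattr(row, "qualifier", "") or ""
        term = row.term_id if not str(qualifier).strip() else NOT_FOUND
        out[row.condition] = term
    return out


def count_headings(variant_conditions: dict[str, tuple[str, ...]],
                   mapping: dict[str, str],
                   hierarchy: MeshHierarchy) -> dict[str, int]:
    """Tally top-level headings across variants, at most once per variant.

    ``variant_conditions`` maps a variant key to its condition strings.
    Conditions missing from the mapping resolve to "Not found".  A variant
    with no conditions contributes nothing.
    """
    counts: dict[str, int] = {}
    for conditions in variant_conditions.values():
        tops: set[str] = set()
        for cond in conditions:
            term = mapping.get(cond, NOT_FOUND)
            if term not in hierarchy:
                logger.warning("mapped term %r not in hierarchy; counting "
                               "as %s", term, NOT_FOUND)
                term = NOT_FOUND
            tops |= hierarchy.ancestors_to_top(term)
        for t in tops:
            counts[t] = counts.get(t, 0) + 1
    return counts


def _covering(tns: set[str], third_tn: str) -> bool:
    prefix = third_tn + "."
    return any(t == third_tn or t.startswith(prefix) for t in tns)


def third_level_coverage(hierarchy: MeshHierarchy,
                         c2u_terms: set[str],
                         predicted_terms: set[str],
                         root_term: str) -> dict:
    """Disease-coverage percentages under one top- or second-level term.

    Enumerates the absolute third-level (depth-3) tree numbers under
    ``root_term``.  A third-level term is covered by editing if any term in
    ``predicted_terms`` maps to it or a descendant, and covered by C>U only
    if terms in ``c2u_terms`` (but none in ``predicted_terms``) do.
    Returns term counts and percentages (None when there are no third-level
    terms).
    """
    if root_term not in hierarchy or root_term == NOT_FOUND:
        raise KeyError(f"unknown root term {root_term!r}")

    def all_tns(terms: set[str]) -> set[str]:
        out: set[str] = set()
        for t in terms:
            if t == NOT_FOUND or t not in hierarchy.tree_numbers:
                continue
            out.update(hierarchy.tree_numbers[t])
        return out

    pred_tns = all_tns(predicted_terms)
    c2u_tns = all_tns(c2u_terms)

    third: set[str] = set()
    for root_tn in hierarchy.tree_numbers[root_term]:
        prefix = root_tn + "."
        for tn in hierarchy.term_at:
            if tn.count(".") == 2 and (tn == root_tn or tn.startswith(prefix)):
                third.add(tn)

    n = len(third)
    if n == 0:
        return {"root": root_term, "n_terms": 0, "n_predicted": 0,
                "n_c2u_only": 0, "pct_predicted": None, "pct_c2u_only": None}
    n_pred = sum(1 for tn in third if _covering(pred_tns, tn))
    n_c2u_only = sum(1 for tn in third
                     if not _covering(pred_tns, tn) and _covering(c2u_tns, tn))
    return {
        "root": root_term,
        "n_terms": n,
        "n_predicted": n_pred,
        "n_c2u_only": n_c2u_only,
        "pct_predicted": 100.0 * n_pred / n,
        "pct_c2u_only": 100.0 * n_c2u_only / n,
    }
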