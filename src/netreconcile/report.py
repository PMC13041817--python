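"""Summary statistics over classified interaction lists.

Two views are reported: the distribution of the new list over categories
and subcategories, and baseline *coverage* — the fraction of baseline edges
touched by at least one corroborating (resp. contradicting) interaction.
Path-mediated classifications attribute coverage to every edge on the
matched path by default (path corroborations are typically the dominant
corroboration subtype, so ignoring them would hide most verified structure);
``path_coverage=False`` restricts coverage to directly matched edges.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .classify import CATEGORIES, ClassifiedInteraction
from .graph import BaselineGraph, Path

__all__ = ["Summary", "summarize"]


@dataclass
class Summary:
    n: int
    category_counts: dict[str, int]
    subcategory_counts: dict[tuple[str, str], int]
    corroborated_edges: int
    contradicted_edges: int
    baseline_edge_count: int

    @property
    def category_fractions(self) -> dict[str, float]:
        if self.n == 0:
            return {c: 0.0 for c in CATEGORIES}
        return {c: self.category_counts.get(c, 0) / self.n for c in CATEGORIES}

    @property
    def corroborated_fraction(self) -> float:
        e = self.baseline_edge_count
        return self.corroborated_edges / e if e else 0.0

    @property
    def contradicted_fraction(self) -> float:
        e = self.baseline_edge_count
        return self.contradicted_edges / e if e else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Delimited-table view: one row per category/subcategory plus the
        two coverage rows; percentages to 0.1%."""
        rows = []
        for cat in CATEGORIES:
            count = self.category_counts.get(cat, 0)
            pct = round(100.0 * count / self.n, 1) if self.n else 0.0
            rows.append({"metric": cat, "count": count, "percent": pct})
            for (c, sub), scount in sorted(self.subcategory_counts.items()):
                if c == cat:
                    spct = round(100.0 * scount / self.n, 1) if self.n else 0.0
                    rows.append({"metric": f"{cat}:{sub}", "count": scount, "percent": spct})
        rows.append({
            "metric": "baseline_corroborated",
            "count": self.corroborated_edges,
            "percent": round(100.0 * self.corroborated_fraction, 1),
        })
        rows.append({
            "metric": "baseline_contradicted",
            "count": self.contradicted_edges,
            "percent": round(100.0 * self.contradicted_fraction, 1),
        })
        return pd.DataFrame(rows, columns=["metric", "count", "percent"])

    def format_text(self) -> str:
        lines = [f"classified interactions: {self.n}"]
        for cat in CATEGORIES:
            count = self.category_counts.get(cat, 0)
            pct = 100.0 * count / self.n if self.n else 0.0
            lines.append(f"  {cat:<14} {count:>6}  ({pct:5.1f}%)")
            for (c, sub), scount in sorted(self.subcategory_counts.items()):
                if c == cat:
                    lines.append(f"    {sub:<16} {scount:>6}")
        lines.append(
            f"baseline coverage: {100.0 * self.corroborated_fraction:.1f}% corroborated, "
            f"{100.0 * self.contradicted_fraction:.1f}% contradicted "
            f"({self.corroborated_edges}/{self.baseline_edge_count} and "
            f"{self.contradicted_edges}/{self.baseline_edge_count} edges)"
        )
        return "\n".join(lines)


def _touched_edges(c: ClassifiedInteraction, path_coverage: bool) -> list[int]:
    if c.matched is None:
        return []
    if isinstance(c.matched, Path):
        return [e.index for e in c.matched.edges] if path_coverage else []
    return [c.matched.index]


def summarize(
    classified: Sequence[ClassifiedInteraction],
    g: BaselineGraph,
    path_coverage: bool = True,
) -> Summary:
    """Aggregate classified interactions into category counts and coverage.

    A baseline edge counts as corroborated (contradicted) if at least one
    classified interaction of that category matched it; with
    ``path_coverage`` every edge on a matched path is marked.
    """
    category_counts: Counter[str] = Counter()
    subcategory_counts: Counter[tuple[str, str]] = Counter()
    corroborated: set[int] = set()
    contradicted: set[int] = set()
    for c in classified:
        category_counts[c.category] += 1
        subcategory_counts[(c.category, c.subcategory)] += 1
        if c.category == "corroboration":
            corroborated.update(_touched_edges(c, path_coverage))
        elif c.category == "contradiction":
            contradicted.update(_touched_edges(c, path_coverage))
    return Summary(
        n=len(classified),
        category_counts=dict(category_counts),
        subcategory_counts=dict(subcategory_counts),
        corroborated_edges=len(corroborated),
        contradicted_edges=len(contradicted),
        baseline_edge_count=g.n_edges,
    )
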