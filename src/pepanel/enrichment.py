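"""Term over-representation among significant proteins (Fisher's exact test).

Each term is tested one-sided for over-representation of the significant
protein set against the background of annotated panel proteins.  The 2x2
table per term is (hits among significant, significant non-hits, background
hits not significant, remaining background).  q-values are BH across the
tested terms; a term is flagged enriched when it has at least 3 hits and
q < 0.1.  Odds ratios are the sample odds ratio, with the Haldane 0.5
correction applied only when a cell is zero.
"""

from __future__ import annotations

import dataclasses

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIN_HITS = 3
Q_THRESHOLD = 0.1


@dataclasses.dataclass
class AnnotationMap:
    """term id -> set of protein symbols, plus optional term names."""

    terms: dict[str, set]
    names: dict[str, str] = dataclasses.field(default_factory=dict)

    def annotated_proteins(self) -> set:
        out: set = set()
        for prots in self.terms.values():
            out |= prots
        return out


@dataclasses.dataclass
class EnrichmentResult:
    table: pd.DataFrame  # term, name, n_hits, hits, odds_ratio, p, q, enriched

    def enriched_terms(self) -> list[str]:
        return self.table.loc[self.table["enriched"], "term"].tolist()

    def summary(self) -> str:
        n = int(self.table["enriched"].sum())
        lines = [f"Enrichment: {n} term(s) enriched (>= {MIN_HITS} hits, q < {Q_THRESHOLD})"]
        for _, r in self.table[self.table["enriched"]].iterrows():
            lines.append(
                f"  {r['term']} ({r['name']}): N={r['n_hits']} OR={r['odds_ratio']:.1f} "
                f"p={r['p']:.3g} q={r['q']:.3g}"
            )
        return "\n".join(lines)


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def enrich(
    significant,
    annotation: AnnotationMap,
    background=None,
    min_hits: int = MIN_HITS,
    q_threshold: float = Q_THRESHOLD,
) -> EnrichmentResult:
    """Over-representation of ``significant`` proteins per annotation term.

    ``background`` defaults to all annotated proteins; the significant set is
    intersected with it (unannotated proteins cannot contribute hits).  An
    empty significant set yields an empty result.  Terms with fewer than
    ``min_hits`` hits are excluded from the report.
    """
    background = set(background) if background is not None else annotation.annotated_proteins()
    sig = set(significant) & background
    cols = ["term", "name", "n_hits", "hits", "odds_ratio", "p", "q", "enriched"]
    if not sig:
        return EnrichmentResult(table=pd.DataFrame(columns=cols))
    n_sig = len(sig)
    n_bg = len(background)
    rows = []
    for term in sorted(annotation.terms):
        members = annotation.terms[term] & background
        hits = sorted(sig & members)
        a = len(hits)
        if a == 0:
            continue
        b = n_sig - a
        c = len(members) - a
        d = n_bg - n_sig - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "term": term,
                "name": annotation.names.get(term, term),
                "n_hits": a,
                "hits": ";".join(hits),
                "odds_ratio": _odds_ratio(a, b, c, d),
                "p": float(p),
            }
        )
    if not rows:
        return EnrichmentResult(table=pd.DataFrame(columns=cols))
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table = table[table["n_hits"] >= min_hits].reset_index(drop=True)
    table["enriched"] = table["q"] < q_threshold
    table = table.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    return EnrichmentResult(table=table[cols] if len(table) else pd.DataFrame(columns=cols))
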