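"""Venn-style candidate gene prediction.

Three gene sets over the analyzed network are intersected:

    A — high network score genes (pooled per-measure top-k),
    B — known disease genes found in the network,
    C — genes annotated to significantly enriched (disease) GO terms.

The prediction rule: genes in both A and C that are not already known
disease genes are the novel candidates, i.e. candidates = (A & C) - B.
The report carries all seven Venn regions so the composition of the
overlap (how many high-score/ontology genes were already known) is
always auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class CandidateReport:
    set_a: frozenset[str]  # high network score
    set_b: frozenset[str]  # known disease genes
    set_c: frozenset[str]  # significant disease ontologies
    candidates: frozenset[str] = field(init=False)
    region_counts: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        a, b, c = self.set_a, self.set_b, self.set_c
        self.candidates = frozenset((a & c) - b)
        self.region_counts = {
            "A_only": len(a - b - c),
            "B_only": len(b - a - c),
            "C_only": len(c - a - b),
            "AB_only": len((a & b) - c),
            "AC_only": len((a & c) - b),
            "BC_only": len((b & c) - a),
            "ABC": len(a & b & c),
        }
        assert len(a & c) == len(a & b & c) + len(self.candidates)
        assert sum(self.region_counts.values()) == len(a | b | c)


def predict_candidates(high_score: set[str], known: set[str],
                       significant_go: set[str]) -> CandidateReport:
    """Apply the Venn prediction rule and account for all seven regions."""
    return CandidateReport(
        set_a=frozenset(high_score),
        set_b=frozenset(known),
        set_c=frozenset(significant_go),
    )


def coverage_summary(known: set[str], high_score: set[str],
                     significant_go: set[str]) -> dict[str, int]:
    """How many known disease genes the two selection routes recover."""
    b = set(known)
    return {
        "known": len(b),
        "known_selected": len(b & (set(high_score) | set(significant_go))),
        "known_high_score": len(b & set(high_score)),
        "known_significant_go": len(b & set(significant_go)),
    }
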