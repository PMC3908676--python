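"""Evaluation of predicted complex sets.

Three metric families: neighbour-affinity matched precision/recall/F-measure
against a reference complex set, the co-localization score (largest fraction
of a complex's annotated members sharing one sub-cellular location), and the
aggregation of precomputed pairwise GO semantic similarities (mean over
member pairs per complex, mean over complexes per ontology, geometric mean
over the cellular-component, biological-process and molecular-function
ontologies).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Optional

from robcomplex.network_io import ComplexSet, LocalizationTable, _data_lines
from robcomplex.scores import neighbour_affinity

# pair -> (sim_cc, sim_bp, sim_mf)
GOSimilarityTable = dict[frozenset[str], tuple[float, float, float]]

DEFAULT_OMEGA = 0.2


@dataclass(frozen=True)
class EvaluationResult:
    """Matching counts and derived ratios of a predicted-vs-reference comparison."""

    n_matched_predicted: int
    n_matched_reference: int
    n_predicted: int
    n_reference: int
    precision: float
    recall: float
    f_measure: float


def complexes_match(p: Iterable[str], b: Iterable[str], omega: float = DEFAULT_OMEGA) -> bool:
    """True when NA(p, b) >= omega (the conventional threshold is 0.2)."""
    if not 0.0 < omega <= 1.0:
        raise ValueError(f"omega must be in (0, 1], got {omega}")
    return neighbour_affinity(p, b) >= omega


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate(P: ComplexSet, B: ComplexSet, omega: float = DEFAULT_OMEGA) -> EvaluationResult:
    """Match predictions P against references B and derive precision/recall/F.

    N_cp counts predicted complexes matching at least one reference; N_cb
    counts references matched by at least one prediction; precision =
    N_cp/|P|, recall = N_cb/|B|.
    """
    if not P or not B:
        raise ValueError("evaluate requires non-empty predicted and reference sets")
    n_cp = sum(1 for p in P if any(complexes_match(p, b, omega) for b in B))
    n_cb = sum(1 for b in B if any(complexes_match(p, b, omega) for p in P))
    precision = n_cp / len(P)
    recall = n_cb / len(B)
    return EvaluationResult(
        n_matched_predicted=n_cp,
        n_matched_reference=n_cb,
        n_predicted=len(P),
        n_reference=len(B),
        precision=precision,
        recall=recall,
        f_measure=f_measure(precision, recall),
    )


def colocalization_score(c: Iterable[str], annot: LocalizationTable) -> Optional[float]:
    """Maximal fraction of annotated members sharing a single location.

    Unannotated proteins are excluded from numerator and denominator;
    returns None when no member is annotated (the complex is skipped).
    """
    members = set(c)
    if not members:
        raise ValueError("complex must be non-empty")
    counts: dict[str, int] = {}
    n_annotated = 0
    for prot in members:
        locs = annot.get(prot)
        if not locs:
            continue
        n_annotated += 1
        for loc in locs:
            counts[loc] = counts.get(loc, 0) + 1
    if n_annotated == 0:
        return None
    return max(counts.values()) / n_annotated


def colocalization_set_score(cs: ComplexSet, annot: LocalizationTable) -> float:
    """Size-weighted co-localization of a complex set.

    Sum of per-complex best location counts over the sum of annotated
    member counts, restricted to complexes with at least one annotated
    member.
    """
    num = 0
    den = 0
    for c in cs:
        counts: dict[str, int] = {}
        n_annotated = 0
        for prot in c:
            locs = annot.get(prot)
            if not locs:
                continue
            n_annotated += 1
            for loc in locs:
                counts[loc] = counts.get(loc, 0) + 1
        if n_annotated == 0:
            continue
        num += max(counts.values())
        den += n_annotated
    if den == 0:
        raise ValueError("no complex has annotated members")
    return num / den


def read_go_similarities(path: str | os.PathLike) -> GOSimilarityTable:
    """Read a pairwise GO similarity TSV: protein_a, protein_b, sim_cc, sim_bp, sim_mf."""
    table: GOSimilarityTable = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 5:
            raise ValueError(f"{path}: line {lineno}: expected 5 tab-separated fields")
        a, b = fields[0].strip(), fields[1].strip()
        try:
            sims = tuple(float(x) for x in fields[2:5])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric similarity") from exc
        if any(not 0.0 <= s <= 1.0 for s in sims):
            raise ValueError(f"{path}: line {lineno}: similarities must lie in [0, 1]")
        table[frozenset((a, b))] = sims  # type: ignore[assignment]
    return table


def go_set_score(cs: ComplexSet, sims: GOSimilarityTable) -> float:
    """Geometric mean over the three ontologies of the set-level GO scores.

    Per complex and ontology: mean pairwise similarity over member pairs
    present in the table (absent pairs are skipped); per ontology: mean over
    complexes with at least one scorable pair.  Raises when nothing is
    scorable.
    """
    per_ontology_totals = [0.0, 0.0, 0.0]
    n_scorable = 0
    for c in cs:
        members = sorted(c)
        pair_sims: list[tuple[float, float, float]] = []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                entry = sims.get(frozenset((members[i], members[j])))
                if entry is not None:
                    pair_sims.append(entry)
        if not pair_sims:
            continue
        n_scorable += 1
        for k in range(3):
            per_ontology_totals[k] += sum(p[k] for p in pair_sims) / len(pair_sims)
    if n_scorable == 0:
        raise ValueError("no complex has scorable member pairs")
    s_cc, s_bp, s_mf = (t / n_scorable for t in per_ontology_totals)
    return (s_cc * s_bp * s_mf) ** (1.0 / 3.0)


def format_report(result: EvaluationResult) -> str:
    """TSV evaluation report: counts, percentages to 2 decimals, raw ratios."""
    header = "Ncp\t|P|\tNcb\t|B|\tPrecision(%)\tRecall(%)\tF-measure(%)\tprecision\trecall\tf_measure"
    row = (
        f"{result.n_matched_predicted}\t{result.n_predicted}\t"
        f"{result.n_matched_reference}\t{result.n_reference}\t"
        f"{100 * result.precision:.2f}\t{100 * result.recall:.2f}\t"
        f"{100 * result.f_measure:.2f}\t"
        f"{result.precision!r}\t{result.recall!r}\t{result.f_measure!r}"
    )
    return header + "\n" + row + "\n"
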