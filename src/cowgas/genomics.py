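"""Comparative arithmetic for hydrogenase/CODH gene loci.

Pairwise protein comparison at the level used for locus orthology screens:
Smith–Waterman local alignment with affine gaps (BLOSUM62, gap open 11,
extend 1), percent identity over the aligned residue pairs, query/subject
coverage of the aligned region, a hard orthology decision rule
(identity > 30% over >= 70% coverage), reciprocal-best-hit pairing of two
loci, average amino acid identity (AAI) of the orthologous pairs, and
signed locus-versus-genome G+C deviation as a horizontal-acquisition
signal.  A seeded protein mutator generates synthetic fixtures at a
controlled target identity.

Alignment conventions
---------------------
* Gap cost: a gap of length k costs ``gap_open + (k - 1) * gap_extend``.
* Identity is computed over aligned residue pairs only (gap columns are
  excluded from numerator and denominator).
* Coverage is the aligned span divided by the full sequence length.
* Among equal-scoring alignments the one ending at the smallest (row,
  column) is reported; traceback ties prefer substitution over a gap in
  the query over a gap in the subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "PROTEIN_ALPHABET",
    "ProteinRecord",
    "AlignmentResult",
    "OrthologyCall",
    "LocusSummary",
    "GCResult",
    "local_align",
    "is_ortholog",
    "reciprocal_best_pairs",
    "average_aai",
    "gc_content",
    "gc_deviation",
    "mutate_protein",
]

#: The 20 canonical residues plus X (unknown).
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_MUTATION_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _matrix_lookup(matrix) -> dict[tuple[str, str], float]:
    alpha = matrix.alphabet
    return {
        (a, b): float(matrix[a, b])
        for a in alpha
        for b in alpha
    }


_BLOSUM62_DICT = _matrix_lookup(_BLOSUM62)


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence (20-letter alphabet plus X)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = set(seq) - set(PROTEIN_ALPHABET)
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains non-amino-acid symbols {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal local alignment of a query/subject pair."""

    query_id: str
    subject_id: str
    score: float
    identity_pct: float  # % identical over aligned residue pairs
    query_coverage: float  # aligned query span / query length
    subject_coverage: float  # aligned subject span / subject length
    query_span: tuple[int, int]  # [start, end) on the query
    subject_span: tuple[int, int]  # [start, end) on the subject

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct outside [0, 100]")
        if not (0.0 <= self.query_coverage <= 1.0 and 0.0 <= self.subject_coverage <= 1.0):
            raise ValueError("coverage outside [0, 1]")


@dataclass(frozen=True)
class OrthologyCall:
    """Binary orthology decision for one protein pair."""

    query_id: str
    subject_id: str
    alignment: AlignmentResult
    is_ortholog: bool
    identity_threshold: float
    coverage_threshold: float


@dataclass(frozen=True)
class LocusSummary:
    """Aggregate of the orthologous pairs between two loci."""

    n_pairs: int
    average_identity_pct: float | None  # None when no orthologous pair exists
    calls: tuple[OrthologyCall, ...]


@dataclass(frozen=True)
class GCResult:
    """Locus G+C content against the genome average, in percentage points."""

    locus_gc_pct: float
    genome_gc_pct: float
    deviation_pp: float  # signed, locus − genome


def local_align(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal Smith–Waterman local alignment with affine gap penalties.

    Gotoh recursion over three states (substitution H, gap-in-subject E,
    gap-in-query F); the reported alignment is the highest-scoring one
    ending at the smallest (row, column).  A pair without any
    positive-scoring alignment yields score 0 and empty spans.
    """
    lookup = _BLOSUM62_DICT if matrix is None else _matrix_lookup(matrix)
    sa, sb = a.sequence, b.sequence
    m, n = len(sa), len(sb)
    neg = -1e30

    h = [[0.0] * (n + 1) for _ in range(m + 1)]
    e = [[neg] * (n + 1) for _ in range(m + 1)]
    f = [[neg] * (n + 1) for _ in range(m + 1)]
    # pointers: 0 none/stop, 1 diag, 2 from E (gap in a), 3 from F (gap in b)
    ptr_h = [[0] * (n + 1) for _ in range(m + 1)]
    ptr_e = [[0] * (n + 1) for _ in range(m + 1)]  # 1 open (from H), 0 extend
    ptr_f = [[0] * (n + 1) for _ in range(m + 1)]

    best, best_i, best_j = 0.0, 0, 0
    for i in range(1, m + 1):
        ai = sa[i - 1]
        hi, him1 = h[i], h[i - 1]
        ei, fi, fim1 = e[i], f[i], f[i - 1]
        for j in range(1, n + 1):
            e_open = hi[j - 1] - gap_open
            e_ext = ei[j - 1] - gap_extend
            if e_open >= e_ext:
                ei[j] = e_open
                ptr_e[i][j] = 1
            else:
                ei[j] = e_ext
            f_open = him1[j] - gap_open
            f_ext = fim1[j] - gap_extend
            if f_open >= f_ext:
                fi[j] = f_open
                ptr_f[i][j] = 1
            else:
                fi[j] = f_ext
            diag = him1[j - 1] + lookup[(ai, sb[j - 1])]
            score, src = 0.0, 0
            if diag > score:
                score, src = diag, 1
            if ei[j] > score:
                score, src = ei[j], 2
            if fi[j] > score:
                score, src = fi[j], 3
            hi[j] = score
            ptr_h[i][j] = src
            if score > best:
                best, best_i, best_j = score, i, j

    if best <= 0.0:
        return AlignmentResult(
            query_id=a.id,
            subject_id=b.id,
            score=0.0,
            identity_pct=0.0,
            query_coverage=0.0,
            subject_coverage=0.0,
            query_span=(0, 0),
            subject_span=(0, 0),
        )

    # traceback
    i, j = best_i, best_j
    state = "H"
    matches = 0
    pairs = 0
    end_i, end_j = i, j
    while i > 0 and j > 0:
        if state == "H":
            src = ptr_h[i][j]
            if src == 0:
                break
            if src == 1:
                pairs += 1
                if sa[i - 1] == sb[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            opened = ptr_e[i][j] == 1
            j -= 1
            if opened:
                state = "H"
        else:  # F
            opened = ptr_f[i][j] == 1
            i -= 1
            if opened:
                state = "H"
    start_i, start_j = i, j

    q_span = (start_i, end_i)
    s_span = (start_j, end_j)
    identity = 100.0 * matches / pairs if pairs else 0.0
    return AlignmentResult(
        query_id=a.id,
        subject_id=b.id,
        score=best,
        identity_pct=identity,
        query_coverage=(end_i - start_i) / m,
        subject_coverage=(end_j - start_j) / n,
        query_span=q_span,
        subject_span=s_span,
    )


def is_ortholog(
    result: AlignmentResult,
    identity_threshold: float = 30.0,
    coverage_threshold: float = 0.70,
    require_both_coverages: bool = False,
) -> OrthologyCall:
    """Apply the hard orthology rule: identity strictly above the threshold
    and query coverage at or above the coverage threshold (optionally
    requiring subject coverage too)."""
    covered = result.query_coverage >= coverage_threshold
    if require_both_coverages:
        covered = covered and result.subject_coverage >= coverage_threshold
    decision = result.identity_pct > identity_threshold and covered
    return OrthologyCall(
        query_id=result.query_id,
        subject_id=result.subject_id,
        alignment=result,
        is_ortholog=decision,
        identity_threshold=identity_threshold,
        coverage_threshold=coverage_threshold,
    )


def reciprocal_best_pairs(
    locus_a: Sequence[ProteinRecord],
    locus_b: Sequence[ProteinRecord],
    identity_threshold: float = 30.0,
    coverage_threshold: float = 0.70,
    **align_kwargs,
) -> list[OrthologyCall]:
    """Mutual best-scoring pairs between two loci that pass the orthology rule.

    Every protein appears in at most one pair; score ties are broken by
    lexicographic id order of the partner.
    """
    if not locus_a or not locus_b:
        raise ValueError("both loci must be non-empty")
    alignments: dict[tuple[str, str], AlignmentResult] = {}
    for pa in locus_a:
        for pb in locus_b:
            alignments[(pa.id, pb.id)] = local_align(pa, pb, **align_kwargs)

    def best_partner(this_id: str, partners: Iterable[ProteinRecord], forward: bool):
        ranked = sorted(
            partners,
            key=lambda p: (
                -(
                    alignments[(this_id, p.id)].score
                    if forward
                    else alignments[(p.id, this_id)].score
                ),
                p.id,
            ),
        )
        return ranked[0].id

    best_a = {pa.id: best_partner(pa.id, locus_b, True) for pa in locus_a}
    best_b = {pb.id: best_partner(pb.id, locus_a, False) for pb in locus_b}

    calls: list[OrthologyCall] = []
    for pa in locus_a:
        partner = best_a[pa.id]
        if best_b[partner] != pa.id:
            continue
        call = is_ortholog(
            alignments[(pa.id, partner)],
            identity_threshold=identity_threshold,
            coverage_threshold=coverage_threshold,
        )
        if call.is_ortholog:
            calls.append(call)
    return calls


def average_aai(calls: Sequence[OrthologyCall]) -> LocusSummary:
    """Average amino acid identity over the orthologous calls."""
    orthologs = [c for c in calls if c.is_ortholog]
    if not orthologs:
        return LocusSummary(n_pairs=0, average_identity_pct=None, calls=tuple(calls))
    mean = sum(c.alignment.identity_pct for c in orthologs) / len(orthologs)
    return LocusSummary(
        n_pairs=len(orthologs), average_identity_pct=mean, calls=tuple(calls)
    )


def gc_content(seq: str) -> float:
    """G+C percentage of a nucleotide sequence; N is excluded from the
    denominator."""
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide symbols {sorted(bad)}")
    denom = sum(s.count(b) for b in "ACGT")
    if denom == 0:
        raise ValueError("empty or all-N nucleotide sequence")
    return 100.0 * (s.count("G") + s.count("C")) / denom


def gc_deviation(locus_seq: str, genome_gc_pct: float) -> GCResult:
    """Signed G+C deviation (percentage points) of a locus from its genome."""
    if not 0.0 <= genome_gc_pct <= 100.0:
        raise ValueError("genome_gc_pct must lie in [0, 100]")
    locus_gc = gc_content(locus_seq)
    return GCResult(
        locus_gc_pct=locus_gc,
        genome_gc_pct=genome_gc_pct,
        deviation_pp=locus_gc - genome_gc_pct,
    )


def mutate_protein(
    seq: str | ProteinRecord,
    target_identity_pct: float,
    seed: int,
    record_id: str | None = None,
    max_rounds: int = 60,
) -> ProteinRecord:
    """Substitute residues until the realized local-alignment identity against
    the original lies within ±2 points of ``target_identity_pct``.

    Positions are taken from a seeded random permutation, so increasing the
    substitution count is monotone; the realized identity is always verified
    with :func:`local_align`.  Raises when the target band is unreachable
    (very short sequences).
    """
    if isinstance(seq, ProteinRecord):
        original = seq
    else:
        original = ProteinRecord(id=record_id or "query", sequence=seq)
    if not 0.0 < target_identity_pct <= 100.0:
        raise ValueError("target identity must be in (0, 100]")
    if target_identity_pct >= 98.0:
        return ProteinRecord(
            id=record_id or f"{original.id}_mut", sequence=original.sequence
        )

    rng = np.random.default_rng(seed)
    length = len(original)
    order = rng.permutation(length)
    residues = list(original.sequence)

    def realize(n_sub: int) -> tuple[str, float]:
        mutated = residues.copy()
        for pos in order[:n_sub]:
            current = mutated[pos]
            choices = [r for r in _MUTATION_ALPHABET if r != current]
            mutated[pos] = choices[int(rng.integers(len(choices)))]
        cand = "".join(mutated)
        ident = local_align(
            original, ProteinRecord(id="cand", sequence=cand)
        ).identity_pct
        return cand, ident

    n_sub = max(1, round(length * (1.0 - target_identity_pct / 100.0)))
    lo, hi = 0, length
    for _ in range(max_rounds):
        candidate, identity = realize(n_sub)
        if abs(identity - target_identity_pct) <= 2.0:
            return ProteinRecord(
                id=record_id or f"{original.id}_mut", sequence=candidate
            )
        if identity > target_identity_pct:
            lo = max(lo, n_sub)
            n_sub = min(hi - 1, n_sub + max(1, (hi - n_sub) // 2))
        else:
            hi = min(hi, n_sub)
            n_sub = max(lo + 1, n_sub - max(1, (n_sub - lo) // 2))
        if hi - lo <= 1 and abs(identity - target_identity_pct) > 2.0:
            raise ValueError(
                f"target identity {target_identity_pct}% unreachable within ±2 "
                f"points on a {length}-residue sequence"
            )
    raise ValueError(
        f"could not realize target identity {target_identity_pct}% in "
        f"{max_rounds} rounds"
    )
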