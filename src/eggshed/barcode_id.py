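"""Species assignment of egg barcode reads.

Implements the survey's identification rules: a read is assigned to a
species when it matches a reference at ≥95% identity with no closely
related alternative, at ≥99% when close relatives exist, or — for
truncated reads of near-identical congener pairs — when it covers at
least two species-diagnostic nucleotide positions and agrees with
exactly one species at all of them.  An in-silico PCR pre-screen
reproduces the amplicon-length shortcut used for the two dominant
species (generic COI amplicon 710 bp; species-specific products 430 and
205 bp).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .io_formats import EggRead, Locus, ReferenceRecord

__all__ = [
    "AssignStatus",
    "AssignMethod",
    "Assignment",
    "DiagnosticSet",
    "PrimerPair",
    "Thresholds",
    "pairwise_identity",
    "find_diagnostic_sites",
    "assign_species",
    "assign_all",
    "insilico_pcr",
    "classify_by_length",
    "marker_bias_tests",
]


class AssignStatus(str, enum.Enum):
    ASSIGNED = "assigned"
    AMBIGUOUS = "ambiguous"
    UNASSIGNED = "unassigned"


class AssignMethod(str, enum.Enum):
    UNIQUE_THRESHOLD = "unique_threshold"
    HIGH_IDENTITY = "high_identity"
    DIAGNOSTIC_SITES = "diagnostic_sites"
    LENGTH_CLASS = "length_class"


@dataclass(frozen=True)
class Assignment:
    read_id: str
    status: AssignStatus
    species: str | None
    best_identity: float
    runner_up_identity: float | None
    method: AssignMethod | None
    diagnostic_covered: int | None = None

    def __post_init__(self) -> None:
        if self.status is AssignStatus.ASSIGNED and (
            self.species is None or self.method is None
        ):
            raise ValueError("assigned reads need a species and a method")
        if not 0.0 <= self.best_identity <= 1.0:
            raise ValueError("best_identity must be a fraction in [0, 1]")


@dataclass(frozen=True)
class DiagnosticSet:
    """Fixed, differing nucleotide states separating two congeners."""

    species_pair: tuple[str, str]
    positions: tuple[int, ...]  # reference-alignment coordinates, increasing
    states: Mapping[str, Mapping[int, str]]  # species -> position -> base

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("diagnostic set needs at least one position")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be strictly increasing")
        a, b = self.species_pair
        for p in self.positions:
            if self.states[a][p] == self.states[b][p]:
                raise ValueError(f"states at position {p} do not differ")


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str
    expected_len: int
    species_specific_for: str | None = None

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")
        if self.expected_len <= max(len(self.forward), len(self.reverse)):
            raise ValueError("expected_len must exceed the primer lengths")


@dataclass(frozen=True)
class Thresholds:
    """Assignment rule thresholds (identity fractions)."""

    min_identity: float = 0.95
    high_identity: float = 0.99
    close_species_margin: float = 0.99  # ref-vs-ref identity defining "close"
    min_diagnostic_coverage: int = 2
    min_aligned_len: int = 150


# ---------------------------------------------------------------------------
# Pairwise identity (semi-global)
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -3.0
    a.extend_gap_score = -1.0
    # free terminal gaps: truncated reads align semi-globally
    a.open_end_insertion_score = 0.0
    a.extend_end_insertion_score = 0.0
    a.open_end_deletion_score = 0.0
    a.extend_end_deletion_score = 0.0
    return a


_ALIGNER = _aligner()


def _alignment_columns(query: str, reference: str) -> tuple[str, str]:
    aln = _ALIGNER.align(query, reference)[0]
    return str(aln[0]), str(aln[1])


def pairwise_identity(query: str, reference: str) -> tuple[float, int]:
    """Fraction identity over the aligned span, terminal gaps free.

    Global alignment with zero-cost end gaps; identity = matches /
    aligned columns after trimming terminal-gap columns (internal gaps
    count as mismatch columns).  Returns (identity, aligned_len).
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    s1, s2 = _alignment_columns(query, reference)
    lo = 0
    hi = len(s1)
    while lo < hi and (s1[lo] == "-" or s2[lo] == "-"):
        lo += 1
    while hi > lo and (s1[hi - 1] == "-" or s2[hi - 1] == "-"):
        hi -= 1
    if hi <= lo:
        return 0.0, 0
    cols = hi - lo
    matches = sum(
        1 for c1, c2 in zip(s1[lo:hi], s2[lo:hi]) if c1 == c2 and c1 != "-"
    )
    return matches / cols, cols


def _map_read_to_reference(read_seq: str, ref_seq: str) -> dict[int, str]:
    """Map reference coordinates -> read base over aligned (non-gap) columns."""
    aln = _ALIGNER.align(read_seq, ref_seq)[0]
    mapping: dict[int, str] = {}
    q, r = aln.aligned  # blocks in query and reference coordinates
    for (q0, q1), (r0, r1) in zip(q, r):
        for offset in range(q1 - q0):
            mapping[r0 + offset] = read_seq[q0 + offset]
    return mapping


# ---------------------------------------------------------------------------
# Diagnostic sites
# ---------------------------------------------------------------------------

def find_diagnostic_sites(
    refs_a: Sequence[str],
    refs_b: Sequence[str],
    species_pair: tuple[str, str] = ("A", "B"),
) -> DiagnosticSet | None:
    """Positions where all of species A's references share one base and all
    of species B's share a different one.

    Coordinates are those of the first A reference (the anchor); other
    sequences are mapped onto it by semi-global alignment.  Returns None
    when no diagnostic position exists.
    """
    if not refs_a or not refs_b:
        raise ValueError("need at least one reference per species")
    anchor = refs_a[0]
    per_seq_states: list[dict[int, str]] = []
    for seq in list(refs_a) + list(refs_b):
        if seq == anchor:
            per_seq_states.append({i: b for i, b in enumerate(anchor)})
        else:
            m = _map_read_to_reference(seq, anchor)
            if not m:
                raise ValueError("unalignable reference sequences")
            per_seq_states.append(m)
    n_a = len(refs_a)
    positions: list[int] = []
    states_a: dict[int, str] = {}
    states_b: dict[int, str] = {}
    for pos in range(len(anchor)):
        col = [m.get(pos) for m in per_seq_states]
        if any(c is None for c in col):
            continue
        a_states = set(col[:n_a])
        b_states = set(col[n_a:])
        if len(a_states) == 1 and len(b_states) == 1 and a_states != b_states:
            positions.append(pos)
            states_a[pos] = next(iter(a_states))
            states_b[pos] = next(iter(b_states))
    if not positions:
        return None
    sa, sb = species_pair
    return DiagnosticSet(
        species_pair=species_pair,
        positions=tuple(positions),
        states={sa: states_a, sb: states_b},
    )


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

class _RefIdentityCache:
    """Reference-vs-reference identities, computed lazily once per pair."""

    def __init__(self, records: Sequence[ReferenceRecord]):
        self._seqs = {r.record_id: r.sequence for r in records}
        self._cache: dict[frozenset, float] = {}

    def identity(self, id_a: str, id_b: str) -> float:
        key = frozenset((id_a, id_b))
        if key not in self._cache:
            ident, _ = pairwise_identity(self._seqs[id_a], self._seqs[id_b])
            self._cache[key] = ident
        return self._cache[key]


def assign_species(
    read: EggRead,
    db: Sequence[ReferenceRecord],
    diagnostics: Sequence[DiagnosticSet] = (),
    thresholds: Thresholds = Thresholds(),
    _ref_cache: _RefIdentityCache | None = None,
) -> Assignment:
    """Assign one read to a species by the identity/diagnostic rule ladder.

    Rule order: (1) rank identity against every same-locus reference;
    (2) best ≥ min_identity with no close second species → assigned
    (unique_threshold); (3) when close species exist, a read covering
    ≥2 diagnostic positions of the top pair and matching exactly one
    species at all of them → assigned (diagnostic_sites) — close
    congeners are separated by their diagnostic nucleotides, so this
    outranks raw identity; (4) otherwise, close species present and
    best ≥ high_identity → assigned (high_identity); (5) best ≥
    min_identity → ambiguous; (6) otherwise unassigned.  Ties between
    species at the top are never broken arbitrarily: they fall through
    to diagnostics or ambiguity.
    """
    locus_db = [r for r in db if r.locus == read.locus]
    if not locus_db:
        raise ValueError(f"no references for locus {read.locus.value}")
    cache = _ref_cache or _RefIdentityCache(locus_db)

    scored = []
    for rec in locus_db:
        ident, alen = pairwise_identity(read.sequence, rec.sequence)
        if alen < thresholds.min_aligned_len:
            continue
        scored.append((ident, alen, rec))
    if not scored:
        return Assignment(read.read_id, AssignStatus.UNASSIGNED, None, 0.0, None, None)
    # best identity per species
    best_by_species: dict[str, tuple[float, ReferenceRecord]] = {}
    for ident, _, rec in scored:
        cur = best_by_species.get(rec.species)
        if cur is None or ident > cur[0]:
            best_by_species[rec.species] = (ident, rec)
    ranked = sorted(best_by_species.items(), key=lambda kv: -kv[1][0])
    best_species, (best_ident, best_rec) = ranked[0]
    runner_ident = ranked[1][1][0] if len(ranked) > 1 else None

    tie = runner_ident is not None and runner_ident == best_ident
    close_species = [
        sp
        for sp, (_, rec) in ranked[1:]
        if cache.identity(rec.record_id, best_rec.record_id)
        >= thresholds.close_species_margin
    ]

    if best_ident >= thresholds.min_identity and not close_species and not tie:
        return Assignment(
            read.read_id,
            AssignStatus.ASSIGNED,
            best_species,
            best_ident,
            runner_ident,
            AssignMethod.UNIQUE_THRESHOLD,
        )
    # diagnostic-site rule for the top pair
    contenders = {best_species, *close_species}
    if tie:
        contenders |= {sp for sp, (ident, _) in ranked if ident == best_ident}
    for dset in diagnostics:
        pa, pb = dset.species_pair
        if pa not in contenders or pb not in contenders:
            continue
        anchor_rec = best_by_species.get(pa, (None, None))[1]
        if anchor_rec is None:
            continue
        read_states = _map_read_to_reference(read.sequence, anchor_rec.sequence)
        covered = [p for p in dset.positions if p in read_states]
        if len(covered) < thresholds.min_diagnostic_coverage:
            continue
        votes = {}
        for sp in (pa, pb):
            votes[sp] = all(read_states[p] == dset.states[sp][p] for p in covered)
        winners = [sp for sp, ok in votes.items() if ok]
        if len(winners) == 1:
            return Assignment(
                read.read_id,
                AssignStatus.ASSIGNED,
                winners[0],
                best_ident,
                runner_ident,
                AssignMethod.DIAGNOSTIC_SITES,
                diagnostic_covered=len(covered),
            )
    if close_species and not tie and best_ident >= thresholds.high_identity:
        return Assignment(
            read.read_id,
            AssignStatus.ASSIGNED,
            best_species,
            best_ident,
            runner_ident,
            AssignMethod.HIGH_IDENTITY,
        )
    if best_ident >= thresholds.min_identity:
        return Assignment(
            read.read_id, AssignStatus.AMBIGUOUS, None, best_ident, runner_ident, None
        )
    return Assignment(
        read.read_id, AssignStatus.UNASSIGNED, None, best_ident, runner_ident, None
    )


def assign_all(
    reads: Iterable[EggRead],
    db: Sequence[ReferenceRecord],
    diagnostics: Sequence[DiagnosticSet] = (),
    thresholds: Thresholds = Thresholds(),
) -> list[Assignment]:
    """Assign a batch of reads, sharing the reference-identity cache."""
    by_locus = {}
    out = []
    for read in reads:
        if read.locus not in by_locus:
            locus_db = [r for r in db if r.locus == read.locus]
            by_locus[read.locus] = _RefIdentityCache(locus_db) if locus_db else None
        out.append(
            assign_species(read, db, diagnostics, thresholds, _ref_cache=by_locus[read.locus])
        )
    return out


def assignments_table(assignments: Sequence[Assignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [a.read_id for a in assignments],
            "status": [a.status.value for a in assignments],
            "species": [a.species for a in assignments],
            "best_identity": [a.best_identity for a in assignments],
            "runner_up_identity": [a.runner_up_identity for a in assignments],
            "method": [a.method.value if a.method else None for a in assignments],
            "diagnostic_covered": [a.diagnostic_covered for a in assignments],
        }
    )


# ---------------------------------------------------------------------------
# In-silico PCR and length classification
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _primer_sites(
    template: str, primer: str, max_mismatch: int, three_prime_exact: int
) -> list[int]:
    """Start offsets where the primer anneals (Hamming, no indels).

    At most ``max_mismatch`` mismatches overall and none within the
    ``three_prime_exact`` 3'-terminal bases of the primer.
    """
    L, k = len(template), len(primer)
    hits = []
    for start in range(L - k + 1):
        window = template[start : start + k]
        mism = sum(1 for a, b in zip(window, primer) if a != b)
        if mism > max_mismatch:
            continue
        tail = sum(
            1
            for a, b in zip(window[k - three_prime_exact :], primer[k - three_prime_exact :])
            if a != b
        )
        if tail == 0:
            hits.append(start)
    return hits


def insilico_pcr(
    template: str,
    primer: PrimerPair,
    max_mismatch: int = 2,
    three_prime_exact: int = 3,
) -> tuple[bool, int | None]:
    """Predict whether a primer pair amplifies the template and the product size.

    The forward primer must anneal upstream of the reverse primer's
    reverse-complement; the product spans the outer primer ends.  The
    shortest feasible product is reported.
    """
    if not template:
        raise ValueError("template must be non-empty")
    fwd_hits = _primer_sites(template, primer.forward, max_mismatch, three_prime_exact)
    if not fwd_hits:
        return False, None
    rc = _revcomp(primer.reverse)
    # the reverse primer's 3' end maps to the *start* of the rc match on
    # the template, so exactness is required at the window head
    rev_hits = [
        s
        for s in range(len(template) - len(rc) + 1)
        if _rev_ok(template, rc, s, max_mismatch, three_prime_exact)
    ]
    best = None
    for f in fwd_hits:
        for r in rev_hits:
            end = r + len(rc)
            if r >= f + len(primer.forward):
                length = end - f
                if best is None or length < best:
                    best = length
    return (best is not None), best


def _rev_ok(template: str, rc: str, start: int, max_mismatch: int, three_prime_exact: int) -> bool:
    window = template[start : start + len(rc)]
    mism = sum(1 for a, b in zip(window, rc) if a != b)
    if mism > max_mismatch:
        return False
    head = sum(1 for a, b in zip(window[:three_prime_exact], rc[:three_prime_exact]) if a != b)
    return head == 0


def classify_by_length(
    product_len: int | None,
    length_classes: Sequence[tuple[int, int, str]],
) -> str | None:
    """Map an amplicon length to the species whose window contains it.

    ``length_classes`` is a sequence of (min_len, max_len, species)
    windows; overlapping windows are a configuration error.  Lengths
    outside every window (e.g. the generic 710 bp product) return None.
    """
    for (lo1, hi1, s1), (lo2, hi2, s2) in itertools.combinations(length_classes, 2):
        if lo1 <= hi2 and lo2 <= hi1:
            raise ValueError(f"overlapping length windows for {s1} and {s2}")
    if product_len is None:
        return None
    for lo, hi, sp in length_classes:
        if lo <= product_len <= hi:
            return sp
    return None


# ---------------------------------------------------------------------------
# Marker-bias comparison (COI vs 16S compositions)
# ---------------------------------------------------------------------------

def marker_bias_tests(
    assignments_coi: Sequence[Assignment],
    assignments_16s: Sequence[Assignment],
) -> dict:
    """Compare species compositions recovered by the two markers.

    For every species seen by either marker, a 2x2 Yates-corrected
    chi-square tests whether its frequency differs between the COI and
    16S assignment sets; a Wilcoxon signed-rank test compares the paired
    rank orders of species frequencies.  Returns a dict with a
    per-species table and the Wilcoxon summary.
    """
    from . import community_stats

    def counts(assignments):
        c: dict[str, int] = {}
        for a in assignments:
            if a.status is AssignStatus.ASSIGNED:
                c[a.species] = c.get(a.species, 0) + 1
        return c

    c1, c2 = counts(assignments_coi), counts(assignments_16s)
    species = sorted(set(c1) | set(c2))
    if len(set(c1) & set(c2)) < 2:
        raise ValueError("fewer than 2 species shared between markers")
    n1, n2 = sum(c1.values()), sum(c2.values())
    rows = []
    for sp in species:
        a, b = c1.get(sp, 0), c2.get(sp, 0)
        table = np.array([[a, n1 - a], [b, n2 - b]])
        try:
            x2, df, p = community_stats.chisq_yates(table)
        except ValueError:  # zero margin (species absent from both)
            x2, df, p = np.nan, 1, np.nan
        rows.append({"species": sp, "coi": a, "s16": b, "chi2_yates": x2, "p": p})
    table_df = pd.DataFrame(rows)

    f1 = np.array([c1.get(sp, 0) / n1 for sp in species])
    f2 = np.array([c2.get(sp, 0) / n2 for sp in species])
    from scipy.stats import rankdata

    r1, r2 = rankdata(f1), rankdata(f2)
    T, n_eff, p_w = community_stats.wilcoxon_signed_rank(r1 - r2)
    return {
        "per_species": table_df,
        "wilcoxon": {"T": T, "n": n_eff, "p": p_w},
    }
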