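"""RT-qPCR primer enumeration, filtering, scoring and pairing.

Candidates are all windows within the length bounds on both strands of a
cDNA template.  Each candidate passes through a fixed filter cascade —
length, GC content, melting temperature, homopolymer runs, hairpin
potential, self-dimer potential — then surviving forward/reverse
candidates are paired under amplicon-length, Tm-difference and cross-dimer
constraints.  Structure checks are exact-complementarity run counting (not
free-energy minimization): deterministic, and strict enough for screening.

Melting temperatures come from the Wallace rule (2(A+T) + 4(G+C)) or,
by default, unified nearest-neighbor thermodynamics with salt correction
(the standard model at qPCR primer lengths).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import MeltingTemp

__all__ = [
    "PrimerCandidate",
    "PrimerPair",
    "PrimerConstraints",
    "gc_fraction",
    "melting_temperature",
    "max_homopolymer_run",
    "hairpin_check",
    "dimer_score",
    "reverse_complement",
    "screen_oligo",
    "design_primers",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def _check_seq(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad or not seq:
        raise ValueError(f"sequence must be non-empty over ACGT (bad: {sorted(bad)})")
    return seq


def reverse_complement(seq: str) -> str:
    return _check_seq(seq).translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Exact (#G + #C) / length."""
    seq = _check_seq(seq)
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(seq: str, method: str = "nearest_neighbor",
                        primer_conc: float = 250e-9,
                        monovalent_salt: float = 50e-3) -> float:
    """Oligo melting temperature in Celsius.

    ``wallace``: 2(#A + #T) + 4(#G + #C), the quick rule for short oligos.
    ``nearest_neighbor``: unified NN thermodynamics (stacked-pair ΔH°/ΔS°
    plus initiation terms), Tm = ΔH°/(ΔS° + R ln(c/4)) − 273.15 with
    monovalent-salt correction; concentrations in molar.
    """
    seq = _check_seq(seq)
    if len(seq) < 2:
        raise ValueError("melting temperature needs length >= 2")
    if method == "wallace":
        return float(MeltingTemp.Tm_Wallace(seq))
    if method == "nearest_neighbor":
        if primer_conc <= 0 or monovalent_salt <= 0:
            raise ValueError("concentrations must be positive")
        return float(MeltingTemp.Tm_NN(seq, dnac1=primer_conc * 1e9 / 2,
                                       dnac2=primer_conc * 1e9 / 2,
                                       Na=monovalent_salt * 1e3))
    raise ValueError(f"unknown Tm method {method!r}")


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-base run."""
    seq = _check_seq(seq)
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def hairpin_check(seq: str, min_stem: int = 4, min_loop: int = 3
                  ) -> tuple[bool, int]:
    """Screen for hairpin potential by exact self-complementarity.

    Flags the oligo if some substring of length >= ``min_stem`` is the
    reverse complement of a downstream substring separated by at least
    ``min_loop`` bases.  Returns (flag, longest qualifying stem length).
    """
    seq = _check_seq(seq)
    if min_stem < 2 or min_loop < 3:
        raise ValueError("need min_stem >= 2 and min_loop >= 3")
    n = len(seq)
    rc = reverse_complement(seq)
    # Longest-common-substring DP between seq and its reverse complement.
    # A run of length R ending at seq index a and rc index b means
    # seq[a-R:a] == revcomp(seq[n-b : n-b+R]): a candidate stem pair whose
    # loop gap is (n - b) - a, constant along the run's diagonal.
    best = 0
    prev = [0] * (n + 1)
    for a in range(1, n + 1):
        cur = [0] * (n + 1)
        ca = seq[a - 1]
        for b in range(1, n + 1):
            if ca == rc[b - 1]:
                run = prev[b - 1] + 1
                cur[b] = run
                if run >= min_stem and (n - b) - a >= min_loop:
                    best = max(best, run)
        prev = cur
    return best >= min_stem, best


def dimer_score(seq1: str, seq2: str) -> int:
    """Longest contiguous Watson-Crick complementary run over all
    antiparallel alignments of two oligos (self-dimer: seq1 == seq2)."""
    seq1 = _check_seq(seq1)
    rc2 = reverse_complement(seq2)  # antiparallel pairing == matching vs rc
    n1, n2 = len(seq1), len(rc2)
    best = 0
    for offset in range(-(n2 - 1), n1):
        run = 0
        for k in range(n2):
            i = offset + k
            if 0 <= i < n1 and seq1[i] == rc2[k]:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


@dataclass
class PrimerConstraints:
    """Screening thresholds for candidate primers and pairs.

    Lengths in bases, GC as fractions, temperatures in Celsius.  Defaults
    are conventional qPCR values; every min must not exceed its max.
    """

    length_min: int = 18
    length_max: int = 25
    gc_min: float = 0.40
    gc_max: float = 0.60
    tm_min: float = 57.0
    tm_max: float = 63.0
    max_tm_difference: float | None = 3.0
    max_run: int | None = 4              # None disables the repeat filter
    hairpin_min_stem: int | None = 4     # None disables the hairpin filter
    hairpin_min_loop: int = 3
    max_dimer_score: int | None = 8      # None disables dimer filters
    amplicon_min: int = 70
    amplicon_max: int = 200
    tm_method: str = "nearest_neighbor"

    def __post_init__(self) -> None:
        for lo, hi, what in [
            (self.length_min, self.length_max, "length"),
            (self.gc_min, self.gc_max, "gc"),
            (self.tm_min, self.tm_max, "tm"),
            (self.amplicon_min, self.amplicon_max, "amplicon"),
        ]:
            if lo > hi:
                raise ValueError(f"{what} min exceeds max")
        if self.length_min < 2:
            raise ValueError("length_min must be >= 2")


@dataclass
class PrimerCandidate:
    sequence: str
    strand: str                 # forward | reverse
    start: int                  # 0-based leftmost template coordinate of the site
    length: int
    gc_fraction: float
    tm_celsius: float
    max_homopolymer_run: int
    hairpin_flag: bool = False
    self_dimer_score: int = 0

    @property
    def end(self) -> int:
        """One past the last template base covered by the primer."""
        return self.start + self.length


@dataclass
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    amplicon_length: int
    tm_difference: float
    cross_dimer_score: int
    pair_score: float

    def as_record(self) -> dict:
        return {
            "forward_seq": self.forward.sequence,
            "forward_start": self.forward.start,
            "reverse_seq": self.reverse.sequence,
            "reverse_start": self.reverse.start,
            "amplicon_length": self.amplicon_length,
            "forward_tm": self.forward.tm_celsius,
            "reverse_tm": self.reverse.tm_celsius,
            "tm_difference": self.tm_difference,
            "cross_dimer_score": self.cross_dimer_score,
            "pair_score": self.pair_score,
        }


@dataclass
class DesignResult:
    pairs: list[PrimerPair]
    attrition: dict[str, int]
    feasibility: np.ndarray | None = None       # code per (fwd, rev) candidate
    forward_candidates: list[PrimerCandidate] = field(default_factory=list)
    reverse_candidates: list[PrimerCandidate] = field(default_factory=list)


# feasibility-matrix codes for a (forward, reverse) candidate combination
FEAS_PASS = 0
FEAS_AMPLICON_SHORT = 1
FEAS_AMPLICON_LONG = 2
FEAS_TM_DIFFERENCE = 3
FEAS_CROSS_DIMER = 4


def screen_oligo(seq: str, constraints: PrimerConstraints
                 ) -> tuple[str, dict]:
    """Run one oligo through the single-primer filter cascade.

    Returns (verdict, properties): verdict is "pass" or the name of the
    first failed filter (gc, tm, run, hairpin, self_dimer); properties
    carries whatever was computed before the failure.
    """
    props: dict = {}
    gc = gc_fraction(seq)
    props["gc"] = gc
    if not constraints.gc_min <= gc <= constraints.gc_max:
        return "gc", props
    tm = melting_temperature(seq, method=constraints.tm_method)
    props["tm"] = tm
    if not constraints.tm_min <= tm <= constraints.tm_max:
        return "tm", props
    run = max_homopolymer_run(seq)
    props["run"] = run
    if constraints.max_run is not None and run > constraints.max_run:
        return "run", props
    props["hairpin"] = False
    if constraints.hairpin_min_stem is not None:
        flag, _stem = hairpin_check(seq, constraints.hairpin_min_stem,
                                    constraints.hairpin_min_loop)
        props["hairpin"] = flag
        if flag:
            return "hairpin", props
    props["self_dimer"] = 0
    if constraints.max_dimer_score is not None:
        sd = dimer_score(seq, seq)
        props["self_dimer"] = sd
        if sd > constraints.max_dimer_score:
            return "self_dimer", props
    return "pass", props


def _enumerate_candidates(template: str, constraints: PrimerConstraints,
                          attrition: dict[str, int]) -> tuple[list, list]:
    """All windows on both strands, run through the filter cascade in
    order: length -> GC -> Tm -> run -> hairpin -> self-dimer."""
    n = len(template)
    fwd: list[PrimerCandidate] = []
    rev: list[PrimerCandidate] = []
    for length in range(constraints.length_min, constraints.length_max + 1):
        for start in range(0, n - length + 1):
            window = template[start:start + length]
            for strand in ("forward", "reverse"):
                seq = window if strand == "forward" else reverse_complement(window)
                attrition["windows"] += 1
                verdict, props = screen_oligo(seq, constraints)
                if verdict != "pass":
                    attrition[verdict] += 1
                    continue
                cand = PrimerCandidate(seq, strand, start, length,
                                       props["gc"], props["tm"], props["run"],
                                       props["hairpin"], props["self_dimer"])
                (fwd if strand == "forward" else rev).append(cand)
    return fwd, rev


def _pair_score(tm_diff: float, amplicon: int, cross: int, self_sum: int,
                constraints: PrimerConstraints) -> float:
    """Higher is better: penalize Tm mismatch, amplicon-length deviation
    from the midpoint of the allowed range, and dimer potential."""
    mid = (constraints.amplicon_min + constraints.amplicon_max) / 2
    span = max(constraints.amplicon_max - constraints.amplicon_min, 1)
    return -(abs(tm_diff)
             + 2.0 * abs(amplicon - mid) / span
             + 0.1 * (cross + self_sum))


def design_primers(template: str, constraints: PrimerConstraints | None = None,
                   top_k: int = 5) -> DesignResult:
    """Enumerate, filter, pair and rank primer pairs on a cDNA template.

    Returns the ``top_k`` pairs by descending pair score plus the full
    forward-candidate x reverse-candidate feasibility matrix coding why
    each combination passed or failed (amplicon bounds, Tm difference,
    cross-dimer) — the data behind a 2-D feasibility plot that exposes
    problematic template regions.  No surviving pair is not an error: the
    result carries per-filter attrition counts instead.
    """
    constraints = constraints or PrimerConstraints()
    template = _check_seq(template)
    if len(template) < constraints.amplicon_min:
        raise ValueError("template shorter than the minimum amplicon length")
    attrition = {k: 0 for k in
                 ("windows", "gc", "tm", "run", "hairpin", "self_dimer",
                  "pairs_tested", "amplicon", "tm_difference", "cross_dimer")}
    fwd, rev = _enumerate_candidates(template, constraints, attrition)
    feas = np.full((len(fwd), len(rev)), -1, dtype=int)
    pairs: list[PrimerPair] = []
    for i, f in enumerate(fwd):
        for j, r in enumerate(rev):
            attrition["pairs_tested"] += 1
            amplicon = r.end - f.start
            if r.start < f.end or amplicon < constraints.amplicon_min:
                feas[i, j] = FEAS_AMPLICON_SHORT
                attrition["amplicon"] += 1
                continue
            if amplicon > constraints.amplicon_max:
                feas[i, j] = FEAS_AMPLICON_LONG
                attrition["amplicon"] += 1
                continue
            tm_diff = f.tm_celsius - r.tm_celsius
            if (constraints.max_tm_difference is not None
                    and abs(tm_diff) > constraints.max_tm_difference):
                feas[i, j] = FEAS_TM_DIFFERENCE
                attrition["tm_difference"] += 1
                continue
            cross = 0
            if constraints.max_dimer_score is not None:
                cross = dimer_score(f.sequence, r.sequence)
                if cross > constraints.max_dimer_score:
                    feas[i, j] = FEAS_CROSS_DIMER
                    attrition["cross_dimer"] += 1
                    continue
            feas[i, j] = FEAS_PASS
            score = _pair_score(tm_diff, amplicon, cross,
                                f.self_dimer_score + r.self_dimer_score,
                                constraints)
            pairs.append(PrimerPair(f, r, amplicon, tm_diff, cross, score))
    pairs.sort(key=lambda p: (-p.pair_score, p.forward.start, p.reverse.start))
    return DesignResult(pairs[:top_k], attrition, feas, fwd, rev)
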