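"""Sequence representation, complementarity, Hamming geometry and master-set
generation for fixed-length RNA-like replicators.

Replicator strands are plain Python strings over the alphabet ``{A, U, G, C}``
with a single fixed length ``L`` per run (default ``L = 10``); there are no
insertions or deletions.  For the compiled simulation core, sequences are
packed into integers with two bits per base (:func:`encode_seq` /
:func:`decode_seq`).

A *master set* is a collection of ``T`` designated fittest sequences (the
genetic information whose maintenance is under study), together with their
complementary strands and their replicabilities.  Three generators are
provided, matching the three experimental designs:

``random``
    Unconstrained random sequences, except that any two masters must differ
    in at least two positions (Hamming distance >= 2) to avoid
    source-sink-type mutational coupling between masters.
``gc_gradient``
    Master ``i`` carries exactly ``i`` G/C bases, so the set spans a GC
    content gradient; all replicabilities equal.
``balanced_gc``
    Every master carries exactly ``L/2`` G/C bases; replicabilities follow
    the linear gradient ``phi_i = phi_min + (i - 1) * delta``.

For the GC-controlled kinds the compositional constraint makes accidental
similarity likely, so bases are reshuffled among loci until every
master-master pair, every master versus another type's complement, and every
master versus its own complement differ in more than three positions (the
last condition also excludes palindromic sequences).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "AUGC"
#: base -> 2-bit code; chosen so the Watson-Crick partner is ``code ^ 1``
BASE_CODE = {"A": 0, "U": 1, "G": 2, "C": 3}
CODE_BASE = {v: k for k, v in BASE_CODE.items()}
WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}

DEFAULT_L = 10
DEFAULT_T = 10
#: bounded rejection sampling: give up (with an error) after this many draws
MAX_ATTEMPTS = 10**6


class ConstraintError(RuntimeError):
    """Raised when rejection sampling cannot satisfy a distance constraint."""


def validate_seq(s: str, length: int | None = None) -> None:
    if not isinstance(s, str) or any(b not in BASE_CODE for b in s):
        raise ValueError(f"invalid nucleotide sequence: {s!r}")
    if length is not None and len(s) != length:
        raise ValueError(f"expected length {length}, got {len(s)}: {s!r}")


def hamming(a: str, b: str) -> int:
    """Number of positions at which *a* and *b* differ."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def complement(s: str, reverse: bool = True) -> str:
    """Watson-Crick complement of *s*.

    With ``reverse=True`` (default) this is the reverse complement, i.e. the
    strand produced by antiparallel template copying.  ``reverse=False``
    gives the positionwise complement, provided for sensitivity checks.
    Either variant is an involution.
    """
    comp = "".join(WC_PARTNER[b] for b in s)
    return comp[::-1] if reverse else comp


def gc_count(s: str) -> int:
    return sum(b in "GC" for b in s)


def encode_seq(s: str) -> int:
    """Pack a sequence into an int, 2 bits per base, position 0 lowest."""
    code = 0
    for k, b in enumerate(s):
        code |= BASE_CODE[b] << (2 * k)
    return code


def decode_seq(code: int, length: int) -> str:
    return "".join(CODE_BASE[(code >> (2 * k)) & 3] for k in range(length))


@dataclass
class MasterSet:
    """``T`` master sequences with complements and replicabilities."""

    masters: list[str]
    complements: list[str]
    replicabilities: list[float]
    generator_kind: str = "random"
    reverse_complement: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        T = len(self.masters)
        if not (len(self.complements) == len(self.replicabilities) == T):
            raise ValueError("masters/complements/replicabilities length mismatch")
        L = len(self.masters[0]) if T else 0
        for m, c in zip(self.masters, self.complements):
            validate_seq(m, L)
            validate_seq(c, L)

    @property
    def T(self) -> int:
        return len(self.masters)

    @property
    def L(self) -> int:
        return len(self.masters[0])

    def gc_contents(self) -> np.ndarray:
        """Relative GC content of each master."""
        return np.array([gc_count(m) / self.L for m in self.masters])

    def check_constraints(self) -> None:
        """Re-audit the distance constraints of this set's generator kind."""
        if self.generator_kind == "random":
            for i in range(self.T):
                for j in range(i + 1, self.T):
                    if hamming(self.masters[i], self.masters[j]) < 2:
                        raise ConstraintError(
                            f"masters {i + 1},{j + 1} closer than Hamming 2"
                        )
        else:
            _check_gc_set_distances(self.masters, self.complements)

    # -- plain-text serialization ------------------------------------------

    def to_fasta(self, path) -> None:
        """Write one FASTA record per master; headers carry index,
        replicability and generator kind."""
        with open(path, "w") as fh:
            for i, (m, phi) in enumerate(zip(self.masters, self.replicabilities), 1):
                fh.write(f">master_{i} replicability={phi:.6g} "
                         f"kind={self.generator_kind}\n{m}\n")

    @classmethod
    def from_fasta(cls, path, reverse_complement: bool = True) -> "MasterSet":
        from Bio import SeqIO

        masters: list[str] = []
        phis: list[float] = []
        kind = "random"
        for rec in SeqIO.parse(str(path), "fasta"):
            masters.append(str(rec.seq).upper().replace("T", "U"))
            phi = 0.005
            for tok in rec.description.split():
                if tok.startswith("replicability="):
                    phi = float(tok.split("=", 1)[1])
                elif tok.startswith("kind="):
                    kind = tok.split("=", 1)[1]
            phis.append(phi)
        comps = [complement(m, reverse_complement) for m in masters]
        return cls(masters, comps, phis, generator_kind=kind,
                   reverse_complement=reverse_complement)


def replicability_gradient(T: int, phi_min: float, delta: float) -> list[float]:
    """Linear replicability landscape ``phi_i = phi_min + (i - 1) * delta``."""
    return [phi_min + i * delta for i in range(T)]


def _random_seq(rng: np.random.Generator, L: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=L))


def generate_master_set(
    T: int = DEFAULT_T,
    L: int = DEFAULT_L,
    seed: int | None = None,
    *,
    phi_min: float = 0.005,
    delta: float = 0.005,
    min_distance: int = 2,
    reverse_complement: bool = True,
    max_attempts: int = MAX_ATTEMPTS,
) -> MasterSet:
    """Random master set with pairwise Hamming distance >= ``min_distance``.

    Sequences are drawn one at a time and rejected while they violate the
    distance constraint against the already-accepted masters; generation is
    reproducible for a fixed *seed*.
    """
    if T < 1 or L < 2:
        raise ValueError("need T >= 1 and L >= 2")
    rng = np.random.default_rng(seed)
    masters: list[str] = []
    attempts = 0
    while len(masters) < T:
        cand = _random_seq(rng, L)
        attempts += 1
        if attempts > max_attempts:
            raise ConstraintError(
                f"could not satisfy Hamming >= {min_distance} after "
                f"{attempts - 1} attempts"
            )
        if all(hamming(cand, m) >= min_distance for m in masters):
            masters.append(cand)
    comps = [complement(m, reverse_complement) for m in masters]
    return MasterSet(masters, comps, replicability_gradient(T, phi_min, delta),
                     generator_kind="random",
                     reverse_complement=reverse_complement, seed=seed)


def _check_gc_set_distances(masters: list[str], comps: list[str],
                            threshold: int = 3) -> None:
    T = len(masters)
    for i in range(T):
        if hamming(masters[i], comps[i]) <= threshold:
            raise ConstraintError(f"master {i + 1} too close to own complement")
        for j in range(i + 1, T):
            if hamming(masters[i], masters[j]) <= threshold:
                raise ConstraintError(f"masters {i + 1},{j + 1} too close")
        for j in range(T):
            if j != i and hamming(masters[i], comps[j]) <= threshold:
                raise ConstraintError(
                    f"master {i + 1} too close to complement of {j + 1}"
                )


def _shuffled_composition_set(
    compositions: list[tuple[int, int]],
    L: int,
    rng: np.random.Generator,
    reverse_complement: bool,
    max_attempts: int,
) -> tuple[list[str], list[str]]:
    """Draw one sequence per (n_GC, n_AU) composition, reshuffling loci until
    all pair classes exceed Hamming distance 3."""
    for _ in range(max_attempts):
        masters = []
        for n_gc, n_au in compositions:
            bases = ["G" if rng.random() < 0.5 else "C" for _ in range(n_gc)]
            bases += ["A" if rng.random() < 0.5 else "U" for _ in range(n_au)]
            bases = list(np.array(bases)[rng.permutation(L)])
            masters.append("".join(bases))
        comps = [complement(m, reverse_complement) for m in masters]
        try:
            _check_gc_set_distances(masters, comps)
        except ConstraintError:
            continue
        return masters, comps
    raise ConstraintError(
        f"could not satisfy Hamming > 3 constraints after {max_attempts} attempts"
    )


def generate_gc_gradient_set(
    T: int = DEFAULT_T,
    L: int = DEFAULT_L,
    seed: int | None = None,
    *,
    phi_equal: float = 0.005,
    reverse_complement: bool = True,
    max_attempts: int = MAX_ATTEMPTS,
) -> MasterSet:
    """Masters along a GC-content gradient: master ``i`` holds exactly ``i``
    G/C bases (G or C with equal probability), the rest A/U; all
    replicabilities equal (default 0.005)."""
    if T > L:
        raise ValueError("GC gradient requires T <= L")
    rng = np.random.default_rng(seed)
    comps_spec = [(i, L - i) for i in range(1, T + 1)]
    masters, comps = _shuffled_composition_set(
        comps_spec, L, rng, reverse_complement, max_attempts)
    return MasterSet(masters, comps, [phi_equal] * T,
                     generator_kind="gc_gradient",
                     reverse_complement=reverse_complement, seed=seed)


def generate_balanced_gc_set(
    T: int = DEFAULT_T,
    L: int = DEFAULT_L,
    delta: float = 0.005,
    seed: int | None = None,
    *,
    phi_min: float = 0.005,
    reverse_complement: bool = True,
    max_attempts: int = MAX_ATTEMPTS,
) -> MasterSet:
    """Masters with identical 50% GC content on a replicability gradient."""
    if L % 2:
        raise ValueError("balanced GC requires even L")
    rng = np.random.default_rng(seed)
    comps_spec = [(L // 2, L // 2)] * T
    masters, comps = _shuffled_composition_set(
        comps_spec, L, rng, reverse_complement, max_attempts)
    return MasterSet(masters, comps, replicability_gradient(T, phi_min, delta),
                     generator_kind="balanced_gc",
                     reverse_complement=reverse_complement, seed=seed)
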