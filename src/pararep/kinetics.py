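"""Sequence-dependent kinetic laws for template-directed replication.

The kinetics couple a replicator's sequence to four rates:

* **replicability** (``c_r``) — the replication rate constant, assigned from
  the linear master landscape ``phi_i = phi_min + (i - 1) * delta`` with
  mutant classes scaled down by Hamming-distance error factors
  (1 error -> 0.2 phi, 2 errors -> 0.05 phi, further -> 0.05 phi_min);
* **dissociation** (``c_d``) — a Boltzmann-type decreasing function of the
  duplex binding energy ``Eb = nAU + 2 nGC`` (G-C pairs count double, so the
  maximum is ``2L``);
* **duplex decay** (``c_dds = f * c_dss * 0.8**Eb``) — duplexes are more
  stable than simplexes, increasingly so at higher binding energy;
* **association** (``c_a = 1``) — sequence independent, but a duplex only
  forms at all when at least two Watson-Crick pairs can form in the fixed
  antiparallel register (no frameshift).

Two dissociation conventions are provided.  The *normalized* form is the
Boltzmann distribution over binding-energy levels
``exp(-kappa*Eb) / sum_{E=2}^{2L} exp(-kappa*E)``; with ``kappa = 0.15`` and
``L = 10`` the strongest duplex dissociates with probability 0.009935.  The
*calibrated* form (default) fixes ``p_diss(2L) = 0.01`` exactly via
``p_diss(Eb) = 0.01**(Eb / 2L)``, which spans [0.01, 0.6309] for
``Eb in [2, 20]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from .sequences import (BASE_CODE, WC_PARTNER, MasterSet, hamming, validate_seq)


@dataclass
class KineticParams:
    """Kinetic constants of a run (defaults follow the standard parameter
    set; rates are in arbitrary reciprocal time units)."""

    phi_min: float = 0.005      #: minimum master replicability
    delta: float = 0.005        #: replicability distance between ranks
    eps1: float = 0.2           #: error factor, Hamming class 1
    eps2: float = 0.05          #: error factor, Hamming class 2
    baseline_factor: float = 0.05  #: times phi_min, for distant mutants
    kappa: float = 0.15         #: inverse-temperature scale (normalized form)
    diss_convention: str = "calibrated"  #: "calibrated" | "normalized"
    diss_target: float = 0.01   #: p_diss at maximum binding energy
    ca: float = 1.0             #: association rate constant
    c_decay_ss: float = 1e-4    #: simplex decay rate (chemostat only)
    f: float = 1.0              #: duplex decay factor, 0 < f <= 1
    p_mut: float = 0.01         #: per-base substitution probability
    min_pairs: int = 2          #: WC pairs needed for a stable duplex
    reverse_complement: bool = True   #: antiparallel pairing register
    include_complements: bool = True  #: minus strands inherit master rates

    def __post_init__(self) -> None:
        if not 0 < self.f <= 1:
            raise ValueError("duplex decay factor must satisfy 0 < f <= 1")
        if not self.eps2 < self.eps1 < 1:
            raise ValueError("error factors must satisfy eps2 < eps1 < 1")
        if not 0 <= self.p_mut <= 1:
            raise ValueError("p_mut must be a probability")
        for name in ("phi_min", "delta", "kappa", "ca", "c_decay_ss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.diss_convention not in ("calibrated", "normalized"):
            raise ValueError(f"unknown convention {self.diss_convention!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DuplexEnergy:
    """Watson-Crick pairing content of a duplex in the fixed register."""

    n_au: int
    n_gc: int

    @property
    def n_pairs(self) -> int:
        return self.n_au + self.n_gc

    @property
    def eb(self) -> int:
        return self.n_au + 2 * self.n_gc


def binding_energy(a: str, b: str, reverse: bool = True) -> DuplexEnergy:
    """Pairing content of the duplex of *a* and *b*.

    With ``reverse=True`` position ``k`` of *a* faces position ``L-1-k`` of
    *b* (antiparallel strands, no frameshift); symmetric in its arguments.
    """
    if len(a) != len(b):
        raise ValueError("strands of a duplex must have equal length")
    other = b[::-1] if reverse else b
    n_au = n_gc = 0
    for x, y in zip(a, other):
        if WC_PARTNER[x] == y:
            if x in "AU":
                n_au += 1
            else:
                n_gc += 1
    return DuplexEnergy(n_au, n_gc)


def association_allowed(e: DuplexEnergy, min_pairs: int = 2) -> bool:
    """A duplex is only stable with at least *min_pairs* WC pairs."""
    return e.n_pairs >= min_pairs


def dissociation_probability(
    eb: float,
    kappa: float = 0.15,
    L: int = 10,
    convention: str = "calibrated",
    target: float = 0.01,
) -> float:
    """Dissociation rate constant ``c_d`` of a duplex with binding energy *eb*.

    ``normalized``: Boltzmann weight over the admissible levels E = 2..2L at
    scale *kappa*.  ``calibrated``: ``target**(eb/2L)``, i.e.
    ``exp(-kappa' * eb)`` with ``kappa' = -ln(target)/(2L)``, which pins the
    maximum-energy duplex at exactly *target*.  Strictly decreasing in *eb*
    under both.
    """
    if not 2 <= eb <= 2 * L:
        raise ValueError(f"binding energy {eb} outside [2, {2 * L}]")
    if convention == "calibrated":
        return target ** (eb / (2 * L))
    if convention == "normalized":
        levels = np.arange(2, 2 * L + 1)
        return math.exp(-kappa * eb) / np.exp(-kappa * levels).sum()
    raise ValueError(f"unknown convention {convention!r}")


def calibrate_kappa(L: int = 10, target: float = 0.01,
                    convention: str = "calibrated") -> float:
    """Scale factor kappa such that ``p_diss(2L) = target``.

    Closed form for the calibrated convention; bracketed root finding on the
    normalized Boltzmann form otherwise.
    """
    if not 0 < target < 1:
        raise ValueError("target must be in (0, 1)")
    if convention == "calibrated":
        return -math.log(target) / (2 * L)

    def resid(kappa: float) -> float:
        return dissociation_probability(2 * L, kappa, L, "normalized") - target

    # p_diss(2L) ranges from 1/(2L-1) (kappa=0) down to ~0 (large kappa)
    lo, hi = 1e-9, 50.0
    if resid(lo) < 0:
        raise ValueError(f"target {target} above the attainable maximum "
                         f"{1 / (2 * L - 1):.4g} for the normalized form")
    return brentq(resid, lo, hi, xtol=1e-12)


def duplex_decay_rate(eb: float, f: float, c_decay_ss: float = 1e-4) -> float:
    """Duplex decay rate ``f * c_dss * 0.8**Eb``; always below the simplex
    decay rate for ``0 < f <= 1`` and ``Eb >= 2``."""
    if not 0 < f <= 1:
        raise ValueError("need 0 < f <= 1")
    if eb < 2:
        raise ValueError("a stable duplex has Eb >= 2")
    return f * c_decay_ss * 0.8 ** eb


def dissociation_table(L: int, kp: KineticParams) -> np.ndarray:
    """``c_d`` indexed by binding energy 0..2L (entries below 2 are 0)."""
    table = np.zeros(2 * L + 1)
    for eb in range(2, 2 * L + 1):
        table[eb] = dissociation_probability(
            eb, kp.kappa, L, kp.diss_convention, kp.diss_target)
    return table


def duplex_decay_table(L: int, kp: KineticParams) -> np.ndarray:
    """``c_dds`` indexed by binding energy 0..2L."""
    table = np.zeros(2 * L + 1)
    for eb in range(2, 2 * L + 1):
        table[eb] = duplex_decay_rate(eb, kp.f, kp.c_decay_ss)
    return table


def type_distance(s: str, ms: MasterSet, i: int,
                  include_complements: bool = True) -> int:
    """Hamming distance of *s* to master type *i* (0-based): the minimum over
    the plus strand and, by default, the minus strand."""
    d = hamming(s, ms.masters[i])
    if include_complements:
        d = min(d, hamming(s, ms.complements[i]))
    return d


def replicability(s: str, ms: MasterSet, kp: KineticParams) -> float:
    """Replication rate constant of an arbitrary sequence.

    For each master type the replicability is scaled by the error factor of
    the Hamming class (0 -> 1, 1 -> eps1, 2 -> eps2); the highest value over
    all types is used.  Sequences further than two errors from every master
    replicate at the baseline ``0.05 * phi_min``.
    """
    validate_seq(s)
    best = kp.baseline_factor * kp.phi_min
    factors = {0: 1.0, 1: kp.eps1, 2: kp.eps2}
    for i in range(ms.T):
        d = type_distance(s, ms, i, kp.include_complements)
        if d <= 2:
            best = max(best, factors[d] * ms.replicabilities[i])
    return best


def mutate_copy(template: str, p_mut: float, rng: np.random.Generator,
                reverse: bool = True) -> str:
    """Template-directed copy: the complement of *template* with each base
    independently substituted with probability *p_mut* (substitutions drawn
    uniformly from the three alternative bases)."""
    from .sequences import complement, ALPHABET

    product = list(complement(template, reverse))
    for k in range(len(product)):
        if rng.random() < p_mut:
            alternatives = [b for b in ALPHABET if b != product[k]]
            product[k] = alternatives[rng.integers(0, 3)]
    return "".join(product)
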