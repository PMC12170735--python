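"""Arithmetic in GF(2^b) and deterministic keyed pseudo-random field elements.

All polynomial evaluations in the multilinear sieve happen over a binary
Galois field GF(2^b).  Elements are plain unsigned integers below ``2**b``:
addition is bitwise XOR (characteristic 2) and multiplication is carry-less
(polynomial) multiplication reduced modulo a fixed irreducible polynomial of
degree ``b``.  One canonical modulus is tabulated per supported width so that
results are reproducible everywhere; any irreducible choice would yield an
isomorphic field, so correctness never depends on the table.

Randomness is supplied by :func:`ff_prf`, a counter-based splitmix-style
mixer: a deterministic function of ``(seed, key)`` with good avalanche
behaviour.  The sieve relies on the same variable receiving the same value
in all ``2**l`` evaluation lanes of one run, which a pseudo-random *function*
guarantees and a stream generator would not.  The contract is determinism
plus approximate uniformity, not cryptographic strength.

Small widths (b = 4, 8) exist to make sieve false negatives frequent enough
to measure; the production default is b = 64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SUPPORTED_WIDTHS",
    "FieldContext",
    "ff_context",
    "ff_add",
    "ff_mul",
    "ff_prf",
    "prf64",
    "prf64_bulk",
    "gf2_poly_is_irreducible",
]

_M64 = (1 << 64) - 1
_GOLD = 0x9E3779B97F4A7C15
_MIX1 = 0xBF58476D1CE4E5B9
_MIX2 = 0x94D049BB133111EB

#: Bit-encoded irreducible modulus per supported width (degree-b term included).
#: 4: x^4+x+1, 8: x^8+x^4+x^3+x+1, 16: x^16+x^5+x^3+x+1,
#: 32: x^32+x^7+x^3+x^2+1, 64: x^64+x^4+x^3+x+1.
_MODULI = {
    4: 0x13,
    8: 0x11B,
    16: 0x1002B,
    32: 0x10000008D,
    64: (1 << 64) | 0x1B,
}

SUPPORTED_WIDTHS = tuple(sorted(_MODULI))


@dataclass(frozen=True)
class FieldContext:
    """A fixed GF(2^b) instance: bit width and bit-encoded modulus polynomial."""

    b: int
    modulus: int

    @property
    def mask(self) -> int:
        """All-ones mask over b bits; also the largest element."""
        return (1 << self.b) - 1

    @property
    def order(self) -> int:
        return 1 << self.b


def ff_context(b: int) -> FieldContext:
    """Return the canonical GF(2^b) context for a supported width."""
    if b not in _MODULI:
        raise ValueError(
            f"unsupported field width b={b}; supported widths are {SUPPORTED_WIDTHS}"
        )
    return FieldContext(b=b, modulus=_MODULI[b])


def ff_add(a: int, c: int) -> int:
    """Field addition: bitwise XOR (its own inverse in characteristic 2)."""
    return a ^ c


def ff_mul(a: int, c: int, ctx: FieldContext) -> int:
    """Carry-less product of ``a`` and ``c`` reduced modulo ``ctx.modulus``.

    Schoolbook shift-and-XOR ("Russian peasant") with interleaved reduction;
    each doubling that overflows degree b-1 is folded back by the modulus.
    """
    b = ctx.b
    top = 1 << b
    r = 0
    while c:
        if c & 1:
            r ^= a
        c >>= 1
        a <<= 1
        if a & top:
            a ^= ctx.modulus
    return r


def _mix64(x: int) -> int:
    """splitmix64 finalizer on a 64-bit integer."""
    x &= _M64
    x ^= x >> 30
    x = (x * _MIX1) & _M64
    x ^= x >> 27
    x = (x * _MIX2) & _M64
    x ^= x >> 31
    return x


def prf64(seed: int, key: tuple[int, ...]) -> int:
    """Deterministic 64-bit value for (seed, key); identical across platforms.

    Each key component is whitened by an odd-constant multiply and absorbed
    into the running state through the splitmix64 finalizer.
    """
    h = _mix64(seed)
    for part in key:
        h = _mix64(h ^ ((part * _GOLD) & _M64))
    return h


def _mix64_np(x: np.ndarray) -> np.ndarray:
    x = x.copy()
    x ^= x >> np.uint64(30)
    x *= np.uint64(_MIX1)
    x ^= x >> np.uint64(27)
    x *= np.uint64(_MIX2)
    x ^= x >> np.uint64(31)
    return x


def prf64_bulk(seed: int, prefix: tuple[int, ...], *arrays: np.ndarray) -> np.ndarray:
    """Vectorized :func:`prf64` over trailing key components.

    ``prf64_bulk(seed, p, a, b)[i] == prf64(seed, p + (a[i], b[i]))``; the
    arrays broadcast against each other.  Negative entries must be masked by
    the caller beforehand (they would wrap module-2^64 silently).
    """
    h = np.uint64(prf64(seed, prefix))
    for a in arrays:
        x = (np.asarray(a, dtype=np.uint64) * np.uint64(_GOLD)) ^ h
        h = _mix64_np(x)
    return np.asarray(h, dtype=np.uint64)


def ff_prf(ctx: FieldContext, seed: int, key: tuple[int, ...]) -> int:
    """A field element drawn deterministically from (seed, key).

    Marginally uniform over [0, 2^b): the 64-bit mixer output is truncated
    to the field width.
    """
    return prf64(seed, key) & ctx.mask


def _poly_deg(p: int) -> int:
    return p.bit_length() - 1


def _poly_mod(a: int, m: int) -> int:
    dm = _poly_deg(m)
    while _poly_deg(a) >= dm:
        a ^= m << (_poly_deg(a) - dm)
    return a


def gf2_poly_is_irreducible(m: int) -> bool:
    """Exhaustive trial division of a bit-encoded polynomial over GF(2).

    Intended for moduli of degree <= 16 (the search space is tiny there);
    a polynomial of degree d is irreducible iff no polynomial of degree
    in [1, d // 2] divides it.
    """
    d = _poly_deg(m)
    if d < 1:
        return False
    for f in range(2, 1 << (d // 2 + 1)):
        if _poly_deg(f) >= 1 and _poly_mod(m, f) == 0:
            return False
    return True
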