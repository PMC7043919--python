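"""Exact integer Laurent polynomials in one variable.

Small, purpose-built arithmetic for knot polynomials: everything is
integer-exact, immutable and hashable.  A polynomial is stored as a
coefficient tuple plus the exponent of its first entry, normalized so the
first and last coefficients are nonzero (the zero polynomial has an empty
tuple).
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Union

Number = Union[int, Fraction]

__all__ = ["LaurentPolynomial"]


class LaurentPolynomial:
    __slots__ = ("coeffs", "minexp")

    def __init__(self, coeffs: Iterable[int] = (), minexp: int = 0):
        cs = [int(c) for c in coeffs]
        lo = 0
        while lo < len(cs) and cs[lo] == 0:
            lo += 1
        hi = len(cs)
        while hi > lo and cs[hi - 1] == 0:
            hi -= 1
        object.__setattr__(self, "coeffs", tuple(cs[lo:hi]))
        object.__setattr__(self, "minexp", minexp + lo if hi > lo else 0)

    # -- constructors ----------------------------------------------------

    @classmethod
    def zero(cls) -> "LaurentPolynomial":
        return cls()

    @classmethod
    def one(cls) -> "LaurentPolynomial":
        return cls((1,))

    @classmethod
    def term(cls, coeff: int, exp: int) -> "LaurentPolynomial":
        return cls((coeff,), exp)

    # -- structure -------------------------------------------------------

    @property
    def is_zero(self) -> bool:
        return not self.coeffs

    @property
    def maxexp(self) -> int:
        return self.minexp + len(self.coeffs) - 1

    @property
    def span(self) -> int:
        """Degree span (maxexp - minexp); 0 for monomials and zero."""
        return len(self.coeffs) - 1 if self.coeffs else 0

    def __getitem__(self, exp: int) -> int:
        k = exp - self.minexp
        if 0 <= k < len(self.coeffs):
            return self.coeffs[k]
        return 0

    def __eq__(self, other) -> bool:
        if not isinstance(other, LaurentPolynomial):
            return NotImplemented
        return self.coeffs == other.coeffs and self.minexp == other.minexp

    def __hash__(self) -> int:
        return hash((self.coeffs, self.minexp))

    def __bool__(self) -> bool:
        return bool(self.coeffs)

    def __repr__(self) -> str:
        if not self.coeffs:
            return "0"
        parts = []
        for k, c in enumerate(self.coeffs):
            if c == 0:
                continue
            e = self.minexp + k
            if e == 0:
                parts.append(f"{c:+d}")
            elif e == 1:
                parts.append(f"{c:+d}*t")
            else:
                parts.append(f"{c:+d}*t^{e}")
        return " ".join(parts)

    # -- arithmetic ------------------------------------------------------

    def __neg__(self) -> "LaurentPolynomial":
        return LaurentPolynomial(tuple(-c for c in self.coeffs), self.minexp)

    def __add__(self, other: "LaurentPolynomial") -> "LaurentPolynomial":
        if self.is_zero:
            return other
        if other.is_zero:
            return self
        lo = min(self.minexp, other.minexp)
        hi = max(self.maxexp, other.maxexp)
        cs = [0] * (hi - lo + 1)
        for k, c in enumerate(self.coeffs):
            cs[self.minexp - lo + k] += c
        for k, c in enumerate(other.coeffs):
            cs[other.minexp - lo + k] += c
        return LaurentPolynomial(cs, lo)

    def __sub__(self, other: "LaurentPolynomial") -> "LaurentPolynomial":
        return self + (-other)

    def __mul__(self, other: "LaurentPolynomial") -> "LaurentPolynomial":
        if self.is_zero or other.is_zero:
            return LaurentPolynomial()
        cs = [0] * (len(self.coeffs) + len(other.coeffs) - 1)
        for i, a in enumerate(self.coeffs):
            if a == 0:
                continue
            for j, b in enumerate(other.coeffs):
                cs[i + j] += a * b
        return LaurentPolynomial(cs, self.minexp + other.minexp)

    def __pow__(self, k: int) -> "LaurentPolynomial":
        if k < 0:
            raise ValueError("negative powers of polynomials are not supported")
        out = LaurentPolynomial.one()
        base = self
        while k:
            if k & 1:
                out = out * base
            base = base * base
            k >>= 1
        return out

    def scale(self, c: int) -> "LaurentPolynomial":
        return LaurentPolynomial(tuple(c * v for v in self.coeffs), self.minexp)

    def shift(self, e: int) -> "LaurentPolynomial":
        """Multiply by t^e."""
        return LaurentPolynomial(self.coeffs, self.minexp + e)

    def exact_div(self, other: "LaurentPolynomial") -> "LaurentPolynomial":
        """Exact division in Z[t, t^-1]; raises if not exact."""
        if other.is_zero:
            raise ZeroDivisionError("division by the zero polynomial")
        if self.is_zero:
            return LaurentPolynomial()
        # Long division over Q from the top, then integrality check.
        rem = list(Fraction(c) for c in self.coeffs)
        div = other.coeffs
        qlen = len(rem) - len(div) + 1
        if qlen <= 0:
            raise ArithmeticError("inexact Laurent division (degree)")
        quot = [Fraction(0)] * qlen
        lead = Fraction(div[-1])
        for k in range(qlen - 1, -1, -1):
            q = rem[k + len(div) - 1] / lead
            quot[k] = q
            if q:
                for j, d in enumerate(div):
                    rem[k + j] -= q * d
        if any(rem):
            raise ArithmeticError("inexact Laurent division (remainder)")
        if any(q.denominator != 1 for q in quot):
            raise ArithmeticError("inexact Laurent division (non-integer quotient)")
        return LaurentPolynomial(
            tuple(int(q) for q in quot), self.minexp - other.minexp
        )

    # -- evaluation and symmetry ----------------------------------------

    def __call__(self, t: Number) -> Fraction:
        tt = Fraction(t)
        if tt == 0:
            raise ZeroDivisionError("Laurent polynomials cannot be evaluated at 0")
        acc = Fraction(0)
        p = tt**self.minexp
        for c in self.coeffs:
            acc += c * p
            p *= tt
        return acc

    def reciprocal(self) -> "LaurentPolynomial":
        """Substitute t -> 1/t."""
        return LaurentPolynomial(tuple(reversed(self.coeffs)), -self.maxexp)

    def is_palindromic(self) -> bool:
        return self.coeffs == tuple(reversed(self.coeffs))

    def centered(self) -> "LaurentPolynomial":
        """Shift so exponents are symmetric about 0 (even span only)."""
        if self.is_zero:
            return self
        if self.span % 2:
            raise ValueError("cannot center a polynomial of odd degree span")
        return LaurentPolynomial(self.coeffs, -(self.span // 2))

    def as_integer_poly(self) -> "LaurentPolynomial":
        """Shift so the lowest exponent is 0."""
        return LaurentPolynomial(self.coeffs, 0)
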