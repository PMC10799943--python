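"""Exact bivariate polynomials in the lattice dimensions m and n.

Every frequency, count and closed-form index formula in this package is a
polynomial in the two expansion parameters of the TCNB(m,n) lattice with
rational coefficients.  The degree never exceeds 2 in either variable (the
coindex identities square the linear edge-count polynomial, nothing in scope
goes further), so the cap is enforced: exceeding it indicates a bug in a
symbolic manipulation, not a legitimate result.

Arithmetic is exact throughout (``fractions.Fraction``); floats are never
accepted as coefficients.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterator, Mapping, Tuple, Union

Exponents = Tuple[int, int]
CoeffLike = Union[int, Fraction, str]

#: maximum exponent per variable; everything in scope fits within it
MAX_DEGREE = 2


def _coerce(value: CoeffLike) -> Fraction:
    if isinstance(value, float):
        raise TypeError("polynomial coefficients must be exact (int, Fraction or string)")
    return Fraction(value)


class BivariatePolynomial:
    """Polynomial in m, n with exact rational coefficients, degree <= 2 per variable.

    Immutable; equality is coefficient-wise.  Construct either from a
    ``{(i, j): coeff}`` mapping or with the :func:`poly` convenience helper.
    """

    __slots__ = ("_coeffs",)

    def __init__(self, coeffs: Mapping[Exponents, CoeffLike] | None = None):
        cleaned: dict[Exponents, Fraction] = {}
        for (i, j), raw in (coeffs or {}).items():
            if not (0 <= i <= MAX_DEGREE and 0 <= j <= MAX_DEGREE):
                raise ValueError(
                    f"monomial m^{i} n^{j} exceeds the degree-{MAX_DEGREE} cap"
                )
            value = _coerce(raw)
            if value:
                cleaned[(int(i), int(j))] = value
        self._coeffs = cleaned

    # -- access ---------------------------------------------------------

    def coefficient(self, i: int, j: int) -> Fraction:
        """Coefficient of m^i n^j (zero if the monomial is absent)."""
        return self._coeffs.get((i, j), Fraction(0))

    def terms(self) -> Iterator[tuple[Exponents, Fraction]]:
        """Monomials in graded-lexicographic order (highest first)."""
        return iter(
            sorted(self._coeffs.items(), key=lambda t: (-(t[0][0] + t[0][1]), -t[0][0]))
        )

    @property
    def is_zero(self) -> bool:
        return not self._coeffs

    def is_integer(self) -> bool:
        """True if every coefficient is an integer."""
        return all(c.denominator == 1 for c in self._coeffs.values())

    # -- arithmetic -----------------------------------------------------

    def __add__(self, other: "BivariatePolynomial | CoeffLike") -> "BivariatePolynomial":
        other = _as_poly(other)
        out = dict(self._coeffs)
        for key, val in other._coeffs.items():
            out[key] = out.get(key, Fraction(0)) + val
        return BivariatePolynomial(out)

    __radd__ = __add__

    def __neg__(self) -> "BivariatePolynomial":
        return BivariatePolynomial({k: -v for k, v in self._coeffs.items()})

    def __sub__(self, other: "BivariatePolynomial | CoeffLike") -> "BivariatePolynomial":
        return self + (-_as_poly(other))

    def __rsub__(self, other: CoeffLike) -> "BivariatePolynomial":
        return _as_poly(other) - self

    def __mul__(self, other: "BivariatePolynomial | CoeffLike") -> "BivariatePolynomial":
        other = _as_poly(other)
        out: dict[Exponents, Fraction] = {}
        for (i1, j1), c1 in self._coeffs.items():
            for (i2, j2), c2 in other._coeffs.items():
                key = (i1 + i2, j1 + j2)
                if key[0] > MAX_DEGREE or key[1] > MAX_DEGREE:
                    raise ValueError(
                        f"product monomial m^{key[0]} n^{key[1]} exceeds the "
                        f"degree-{MAX_DEGREE} cap"
                    )
                out[key] = out.get(key, Fraction(0)) + c1 * c2
        return BivariatePolynomial(out)

    __rmul__ = __mul__

    def __call__(self, m: int | Fraction, n: int | Fraction) -> Fraction:
        """Exact substitution."""
        total = Fraction(0)
        for (i, j), c in self._coeffs.items():
            total += c * Fraction(m) ** i * Fraction(n) ** j
        return total

    # -- comparison / hashing ------------------------------------------

    def __eq__(self, other: object) -> bool:
        if isinstance(other, (int, Fraction)):
            other = _as_poly(other)
        if not isinstance(other, BivariatePolynomial):
            return NotImplemented
        return self._coeffs == other._coeffs

    def __hash__(self) -> int:
        return hash(frozenset(self._coeffs.items()))

    # -- rendering / serialization -------------------------------------

    def __str__(self) -> str:
        if self.is_zero:
            return "0"
        parts = []
        for (i, j), c in self.terms():
            mono = "".join(
                s
                for s in (
                    "m" if i == 1 else f"m^{i}" if i else "",
                    "n" if j == 1 else f"n^{j}" if j else "",
                )
                if s
            )
            if not mono:
                piece = str(c)
            elif c == 1:
                piece = mono
            elif c == -1:
                piece = f"-{mono}"
            else:
                piece = f"{c}*{mono}"
            parts.append(piece)
        text = " + ".join(parts)
        return text.replace("+ -", "- ")

    def __repr__(self) -> str:
        return f"BivariatePolynomial({self})"

    def to_coeff_map(self) -> dict[str, str]:
        """Plain-text form: ``{"i,j": "p/q"}`` with zero terms omitted."""
        return {f"{i},{j}": str(c) for (i, j), c in sorted(self._coeffs.items())}

    @classmethod
    def from_coeff_map(cls, data: Mapping[str, CoeffLike]) -> "BivariatePolynomial":
        coeffs: dict[Exponents, CoeffLike] = {}
        for key, val in data.items():
            i_str, j_str = str(key).split(",")
            coeffs[(int(i_str), int(j_str))] = val
        return cls(coeffs)


def _as_poly(value: "BivariatePolynomial | CoeffLike") -> BivariatePolynomial:
    if isinstance(value, BivariatePolynomial):
        return value
    return BivariatePolynomial({(0, 0): value})


def poly(
    const: CoeffLike = 0,
    m: CoeffLike = 0,
    n: CoeffLike = 0,
    mn: CoeffLike = 0,
    m2: CoeffLike = 0,
    n2: CoeffLike = 0,
    m2n: CoeffLike = 0,
    mn2: CoeffLike = 0,
    m2n2: CoeffLike = 0,
) -> BivariatePolynomial:
    """Build a polynomial from named monomial coefficients (a*mn + b*m + ...)."""
    return BivariatePolynomial(
        {
            (0, 0): const,
            (1, 0): m,
            (0, 1): n,
            (1, 1): mn,
            (2, 0): m2,
            (0, 2): n2,
            (2, 1): m2n,
            (1, 2): mn2,
            (2, 2): m2n2,
        }
    )


ZERO = BivariatePolynomial()
ONE = poly(const=1)
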