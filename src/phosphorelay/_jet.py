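"""Second-order forward-mode differentiation (truncated Taylor jets).

A :class:`Jet` carries a value together with first and second derivatives
with respect to a single scalar.  Propagating a jet through the rational
steady-state elimination gives derivatives of the signal function f that are
exact to machine precision, which is what the curvature-sign classifier
needs.  Components may be floats or numpy arrays (element-wise jets).
"""

from __future__ import annotations

import math


class Jet:
    __slots__ = ("f", "d1", "d2")

    def __init__(self, f, d1=0.0, d2=0.0):
        self.f = f
        self.d1 = d1
        self.d2 = d2

    @classmethod
    def variable(cls, x):
        """The differentiation variable itself (derivative 1)."""
        return cls(x, 1.0, 0.0)

    def __add__(self, other):
        if isinstance(other, Jet):
            return Jet(self.f + other.f, self.d1 + other.d1, self.d2 + other.d2)
        return Jet(self.f + other, self.d1, self.d2)

    __radd__ = __add__

    def __neg__(self):
        return Jet(-self.f, -self.d1, -self.d2)

    def __sub__(self, other):
        if isinstance(other, Jet):
            return Jet(self.f - other.f, self.d1 - other.d1, self.d2 - other.d2)
        return Jet(self.f - other, self.d1, self.d2)

    def __rsub__(self, other):
        return Jet(other - self.f, -self.d1, -self.d2)

    def __mul__(self, other):
        if isinstance(other, Jet):
            return Jet(
                self.f * other.f,
                self.d1 * other.f + self.f * other.d1,
                self.d2 * other.f + 2.0 * self.d1 * other.d1 + self.f * other.d2,
            )
        return Jet(self.f * other, self.d1 * other, self.d2 * other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if not isinstance(other, Jet):
            inv = 1.0 / other
            return Jet(self.f * inv, self.d1 * inv, self.d2 * inv)
        q0 = self.f / other.f
        q1 = (self.d1 - q0 * other.d1) / other.f
        q2 = (self.d2 - 2.0 * q1 * other.d1 - q0 * other.d2) / other.f
        return Jet(q0, q1, q2)

    def __rtruediv__(self, other):
        return Jet(other) / self

    def sqrt(self):
        r0 = math.sqrt(self.f) if not hasattr(self.f, "__len__") else self.f ** 0.5
        r1 = self.d1 / (2.0 * r0)
        r2 = (self.d2 - 2.0 * r1 * r1) / (2.0 * r0)
        return Jet(r0, r1, r2)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Jet({self.f!r}, {self.d1!r}, {self.d2!r})"
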