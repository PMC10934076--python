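"""Shortened binary BCH codes over GF(2^m).

Provides exactly what the code-offset fuzzy extractor needs: a systematic
binary BCH code of natural length n = 2^m - 1, shortened to the seed length,
with designed correction capacity t. Encoding is polynomial division by the
generator polynomial; decoding computes syndromes, runs Berlekamp-Massey for
the error locator and a Chien search for the error positions.

Bit convention: bit ``i`` of a codeword array is the coefficient of x^i.
Parity occupies the low-order coefficients (0 .. n-k-1), message bits the
next k_short coefficients, and the shortened (implicitly zero) positions are
the high-order ones.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .exceptions import CodeParameterError, ReproductionError

# primitive polynomials for GF(2^m), bit i = coefficient of x^i
_PRIM_POLY = {3: 0b1011, 4: 0b10011, 5: 0b100101, 6: 0b1000011,
              7: 0b10001001, 8: 0b100011101}


class _GF:
    """GF(2^m) arithmetic via log/antilog tables."""

    def __init__(self, m: int):
        self.m = m
        self.n = (1 << m) - 1
        poly = _PRIM_POLY[m]
        self.exp = np.zeros(2 * self.n, dtype=np.int64)
        self.log = np.zeros(self.n + 1, dtype=np.int64)
        x = 1
        for i in range(self.n):
            self.exp[i] = x
            self.log[x] = i
            x <<= 1
            if x & (1 << m):
                x ^= poly
        self.exp[self.n:2 * self.n] = self.exp[:self.n]

    def mul(self, a: int, b: int) -> int:
        if a == 0 or b == 0:
            return 0
        return int(self.exp[self.log[a] + self.log[b]])

    def inv(self, a: int) -> int:
        if a == 0:
            raise ZeroDivisionError("GF inverse of 0")
        return int(self.exp[self.n - self.log[a]])

    def pow_alpha(self, e: int) -> int:
        return int(self.exp[e % self.n])


def _poly_mul_gf2(a: int, b: int) -> int:
    """Carry-less product of two GF(2)[x] polynomials as bit masks."""
    out = 0
    while b:
        if b & 1:
            out ^= a
        a <<= 1
        b >>= 1
    return out


def _poly_mod_gf2(a: int, g: int) -> int:
    dg = g.bit_length() - 1
    while a.bit_length() - 1 >= dg and a:
        a ^= g << (a.bit_length() - 1 - dg)
    return a


def _minimal_poly(gf: _GF, i: int) -> int:
    """Minimal polynomial of alpha^i over GF(2), as a bit mask."""
    coset = set()
    c = i % gf.n
    while c not in coset:
        coset.add(c)
        c = (c * 2) % gf.n
    # prod (x - alpha^c): coefficients live in GF(2^m), end binary
    poly = [1]  # ascending coefficients, GF elements
    for c in sorted(coset):
        root = gf.pow_alpha(c)
        new = [0] * (len(poly) + 1)
        for d, coeff in enumerate(poly):
            new[d + 1] ^= coeff                 # x * poly
            new[d] ^= gf.mul(coeff, root)       # root * poly
        poly = new
    mask = 0
    for d, coeff in enumerate(poly):
        if coeff not in (0, 1):
            raise AssertionError("minimal polynomial not binary")
        mask |= coeff << d
    return mask


class BCH:
    """Binary BCH code of designed correction capacity t, shortened to
    ``n_bits`` transmitted bits."""

    def __init__(self, n_bits: int, t: int):
        if t < 1:
            raise CodeParameterError("t must be >= 1")
        m = next((m for m in sorted(_PRIM_POLY) if (1 << m) - 1 >= n_bits), None)
        if m is None:
            raise CodeParameterError(f"n_bits={n_bits} exceeds supported codes")
        self.gf = _GF(m)
        self.n = self.gf.n
        self.n_bits = int(n_bits)
        self.t = int(t)

        g = 1
        seen: set[int] = set()
        for i in range(1, 2 * t + 1):
            c = i % self.n
            coset_min = min({(c * (1 << j)) % self.n
                             for j in range(self.gf.m)})
            if coset_min in seen:
                continue
            seen.add(coset_min)
            g = _poly_mul_gf2(g, _minimal_poly(self.gf, i))
        self.g = g
        self.k = self.n - (g.bit_length() - 1)
        self.k_short = self.k - (self.n - self.n_bits)
        if self.k_short < 1:
            opts = self._feasible_options()
            raise CodeParameterError(
                f"no BCH({self.n}) achieves t={t} at length {n_bits}; "
                f"feasible (t, message bits): {opts}")

    def _feasible_options(self) -> list[tuple[int, int]]:
        opts = []
        for tt in range(1, self.t):
            try:
                code = BCH(self.n_bits, tt)
                opts.append((tt, code.k_short))
            except CodeParameterError:
                break
        return opts

    # ------------------------------------------------------------------
    def encode(self, message: np.ndarray) -> np.ndarray:
        """Systematic encoding of ``k_short`` message bits."""
        msg = np.asarray(message, dtype=np.uint8)
        if msg.shape != (self.k_short,):
            raise CodeParameterError(
                f"message must have {self.k_short} bits, got {msg.shape}")
        n_parity = self.n - self.k
        m_int = 0
        for i, bit in enumerate(msg):
            if bit:
                m_int |= 1 << (n_parity + i)
        parity = _poly_mod_gf2(m_int, self.g)
        cw = m_int ^ parity
        out = np.zeros(self.n_bits, dtype=np.uint8)
        for i in range(self.n_bits):
            out[i] = (cw >> i) & 1
        return out

    def _syndromes(self, bits: np.ndarray) -> np.ndarray:
        pos = np.nonzero(bits)[0]
        S = np.zeros(2 * self.t, dtype=np.int64)
        if pos.size == 0:
            return S
        for i in range(1, 2 * self.t + 1):
            terms = self.gf.exp[(i * pos) % self.n]
            S[i - 1] = int(np.bitwise_xor.reduce(terms))
        return S

    def _berlekamp_massey(self, S: np.ndarray) -> list[int]:
        gf = self.gf
        nn = 2 * self.t
        C = [0] * (nn + 1)
        B = [0] * (nn + 1)
        C[0] = B[0] = 1
        L, m_, b = 0, 1, 1
        for n_ in range(nn):
            d = int(S[n_])
            for i in range(1, L + 1):
                d ^= gf.mul(C[i], int(S[n_ - i]))
            if d == 0:
                m_ += 1
                continue
            coef = gf.mul(d, gf.inv(b))
            if 2 * L <= n_:
                T = C.copy()
                for i in range(0, nn + 1 - m_):
                    C[i + m_] ^= gf.mul(coef, B[i])
                L, B, b, m_ = n_ + 1 - L, T, d, 1
            else:
                for i in range(0, nn + 1 - m_):
                    C[i + m_] ^= gf.mul(coef, B[i])
                m_ += 1
        return C[:L + 1]

    def decode(self, received: np.ndarray) -> tuple[np.ndarray, int]:
        """Correct up to t errors; return (message bits, #errors).

        Raises ReproductionError when decoding fails (more errors than the
        code can locate, or locations in the shortened region).
        """
        r = np.asarray(received, dtype=np.uint8)
        if r.shape != (self.n_bits,):
            raise CodeParameterError(
                f"received word must have {self.n_bits} bits")
        S = self._syndromes(r)
        corrected = r.copy()
        n_err = 0
        if np.any(S):
            sigma = self._berlekamp_massey(S)
            L = len(sigma) - 1
            if L == 0 or L > self.t:
                raise ReproductionError("error locator degree out of range")
            # Chien search over all n positions
            gf = self.gf
            p_all = np.arange(self.n)
            val = np.full(self.n, sigma[0], dtype=np.int64)
            for i in range(1, L + 1):
                if sigma[i] == 0:
                    continue
                e = (gf.log[sigma[i]] + (-p_all * i) % self.n) % self.n
                val ^= gf.exp[e]
            roots = p_all[val == 0]
            if roots.size != L:
                raise ReproductionError("error locator has missing roots")
            if np.any(roots >= self.n_bits):
                raise ReproductionError("error located in the shortened region")
            corrected[roots] ^= 1
            n_err = int(L)
            if np.any(self._syndromes(corrected)):
                raise ReproductionError("correction did not zero the syndromes")
        n_parity = self.n - self.k
        msg = corrected[n_parity:n_parity + self.k_short].copy()
        return msg, n_err


@lru_cache(maxsize=64)
def get_code(n_bits: int, t: int) -> BCH:
    """Memoized code constructor (GF tables are reusable and immutable)."""
    return BCH(n_bits, t)
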