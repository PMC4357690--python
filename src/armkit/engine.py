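"""Primer-design engines.

The pipeline treats primer design as a plug-in contract: given a window
sequence, a product-size range and a pair budget, an engine returns scored
primer pairs.  The shipped :class:`ThermoEngine` is a deterministic,
dependency-free engine that scores primers by nearest-neighbor duplex
thermodynamics (SantaLucia 1998 unified parameters) plus GC and length terms,
with the pair penalty the weighted deviation of both primers from their
optima.  A wrapper around an external engine such as Primer3 can be dropped in
wherever one is installed; every downstream stage sees only the contract.

Scoring is fully vectorized: dinucleotide enthalpy/entropy prefix sums over
the window let every (start, length) candidate be evaluated at once, and the
best candidate per start (forward) / per end (reverse) position is kept.  Any
base that is lowercase (soft-masked repeat) or not A/C/G/T disqualifies every
primer covering it — the repeat filter the arm factory relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

_R = 1.987  # cal/(mol K)

# SantaLucia (1998) unified NN parameters, dH kcal/mol, dS cal/(mol K),
# indexed by 4*first+second with A=0, C=1, G=2, T=3.
_NN_DH = np.zeros(16)
_NN_DS = np.zeros(16)
for _pair, (_dh, _ds) in {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "AC": (-8.4, -22.4),
    "AG": (-7.8, -21.0), "TA": (-7.2, -21.3), "TT": (-7.9, -22.2),
    "TC": (-8.2, -22.2), "TG": (-8.5, -22.7), "CA": (-8.5, -22.7),
    "CT": (-7.8, -21.0), "CC": (-8.0, -19.9), "CG": (-10.6, -27.2),
    "GA": (-8.2, -22.2), "GT": (-8.4, -22.4), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}.items():
    _idx = "ACGT".index(_pair[0]) * 4 + "ACGT".index(_pair[1])
    _NN_DH[_idx] = _dh
    _NN_DS[_idx] = _ds

# terminal initiation terms: index by base code, A/T vs G/C ends
_INIT_DH = np.array([2.3, 0.1, 0.1, 2.3])
_INIT_DS = np.array([4.1, -2.8, -2.8, 4.1])

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnginePair:
    """A primer pair in window-relative coordinates.

    ``fwd`` occupies [fwd_start, fwd_end) on the plus strand; ``rev`` is the
    reverse complement of [rev_start, rev_end); the PCR product is
    [fwd_start, rev_end).
    """

    fwd_seq: str
    fwd_start: int
    fwd_end: int
    rev_seq: str
    rev_start: int
    rev_end: int
    penalty: float


class PrimerEngine(Protocol):
    def design(
        self, window_seq: str, size_range: tuple[int, int], npp: int
    ) -> list[EnginePair]:
        """Return up to ``npp`` pairs with product length inside ``size_range``
        (half-open), best first, deterministically."""
        ...


class ThermoEngine:
    """Deterministic nearest-neighbor thermodynamic primer engine.

    Parameters mirror common primer-design defaults: optimum melting
    temperature 60 degC, optimum length 20 nt, optimum GC 50%, monovalent salt
    50 mM, primer concentration 50 nM.  The single-primer penalty is

        |Tm - 60| + 0.3 |len - 20| + 0.05 |GC% - 50|

    and a pair adds 0.5 |Tm_fwd - Tm_rev|.  Identical inputs always produce
    identical output: ties are broken by (penalty, forward start, reverse end).
    """

    def __init__(
        self,
        primer_len: tuple[int, int] = (18, 30),
        opt_tm: float = 60.0,
        opt_len: int = 20,
        opt_gc: float = 50.0,
        na_molar: float = 0.05,
        primer_conc: float = 5e-8,
        w_tm: float = 1.0,
        w_len: float = 0.3,
        w_gc: float = 0.05,
        w_pair_tm: float = 0.5,
    ):
        self.primer_len = primer_len
        self.opt_tm = opt_tm
        self.opt_len = opt_len
        self.opt_gc = opt_gc
        self.na_molar = na_molar
        self.primer_conc = primer_conc
        self.w_tm, self.w_len, self.w_gc = w_tm, w_len, w_gc
        self.w_pair_tm = w_pair_tm
        self._cache: tuple[str, tuple] | None = None

    # -- single-primer scoring -------------------------------------------
    def melting_temperature(self, seq: str) -> float:
        """NN duplex Tm (degC) with salt-corrected entropy; strand-symmetric."""
        codes = _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
        if (codes < 0).any() or len(codes) < 2:
            raise ValueError("Tm defined only for pure ACGT sequences, len>=2")
        dinuc = codes[:-1] * 4 + codes[1:]
        dh = _NN_DH[dinuc].sum() + _INIT_DH[codes[0]] + _INIT_DH[codes[-1]]
        ds = _NN_DS[dinuc].sum() + _INIT_DS[codes[0]] + _INIT_DS[codes[-1]]
        ds += 0.368 * (len(codes) - 1) * np.log(self.na_molar)
        return 1000.0 * dh / (ds + _R * np.log(self.primer_conc / 4.0)) - 273.15

    def _score_window(self, seq: str):
        """Best primer per forward-start and per reverse-end position.

        Returns arrays of length n (+1 for ends): penalty, primer length and
        Tm, with +inf penalty where no valid primer exists.
        """
        if self._cache is not None and self._cache[0] == seq:
            return self._cache[1]
        n = len(seq)
        codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        valid = codes >= 0  # uppercase ACGT only: masked/N bases disqualify
        bad_pre = np.concatenate(([0], np.cumsum(~valid)))
        gc_pre = np.concatenate(([0], np.cumsum((codes == 1) | (codes == 2))))
        safe = np.where(valid, codes, 0)
        dinuc = safe[:-1] * 4 + safe[1:] if n > 1 else np.empty(0, dtype=int)
        dh_pre = np.concatenate(([0.0], np.cumsum(_NN_DH[dinuc])))
        ds_pre = np.concatenate(([0.0], np.cumsum(_NN_DS[dinuc])))

        lo, hi = self.primer_len
        f_pen = np.full(n + 1, np.inf)
        f_len = np.zeros(n + 1, dtype=np.int32)
        f_tm = np.zeros(n + 1)
        r_pen = np.full(n + 1, np.inf)
        r_len = np.zeros(n + 1, dtype=np.int32)
        r_tm = np.zeros(n + 1)
        log_ct = _R * np.log(self.primer_conc / 4.0)
        for length in range(lo, min(hi, n) + 1):
            s = np.arange(0, n - length + 1)
            ok = (bad_pre[s + length] - bad_pre[s]) == 0
            if not ok.any():
                continue
            dh = (
                dh_pre[s + length - 1]
                - dh_pre[s]
                + _INIT_DH[safe[s]]
                + _INIT_DH[safe[s + length - 1]]
            )
            ds = (
                ds_pre[s + length - 1]
                - ds_pre[s]
                + _INIT_DS[safe[s]]
                + _INIT_DS[safe[s + length - 1]]
                + 0.368 * (length - 1) * np.log(self.na_molar)
            )
            tm = 1000.0 * dh / (ds + log_ct) - 273.15
            gc_pct = 100.0 * (gc_pre[s + length] - gc_pre[s]) / length
            pen = (
                self.w_tm * np.abs(tm - self.opt_tm)
                + self.w_len * abs(length - self.opt_len)
                + self.w_gc * np.abs(gc_pct - self.opt_gc)
            )
            pen = np.where(ok, pen, np.inf)
            upd = pen < f_pen[s]
            f_pen[s[upd]] = pen[upd]
            f_len[s[upd]] = length
            f_tm[s[upd]] = tm[upd]
            e = s + length
            upd = pen < r_pen[e]
            r_pen[e[upd]] = pen[upd]
            r_len[e[upd]] = length
            r_tm[e[upd]] = tm[upd]
        result = (f_pen, f_len, f_tm, r_pen, r_len, r_tm)
        self._cache = (seq, result)
        return result

    # -- pair design ------------------------------------------------------
    def design(
        self, window_seq: str, size_range: tuple[int, int], npp: int
    ) -> list[EnginePair]:
        n = len(window_seq)
        lo, hi = size_range
        if n < lo or npp < 1:
            return []
        f_pen, f_len, f_tm, r_pen, r_len, r_tm = self._score_window(window_seq)
        width = min(hi, n + 1) - lo
        if width <= 0:
            return []
        pad = np.full(lo + width, np.inf)
        r_pen_p = np.concatenate((r_pen, pad))
        r_tm_p = np.concatenate((r_tm, np.zeros(lo + width)))
        starts = np.nonzero(np.isfinite(f_pen[:n]))[0]
        if starts.size == 0:
            return []
        # candidate reverse ends for start s are e = s + lo .. s + lo + width - 1
        win = np.lib.stride_tricks.sliding_window_view(r_pen_p, width)
        tm_win = np.lib.stride_tricks.sliding_window_view(r_tm_p, width)
        pair_pen = (
            f_pen[starts, None]
            + win[starts + lo]
            + self.w_pair_tm * np.abs(f_tm[starts, None] - tm_win[starts + lo])
        )
        si, di = np.nonzero(np.isfinite(pair_pen))
        if si.size == 0:
            return []
        s = starts[si]
        e = s + lo + di
        pen = pair_pen[si, di]
        # exact top-npp under (penalty, start, end): partition by penalty,
        # then lexsort only the candidates at or below the cutoff value
        if pen.size > npp:
            cutoff = np.partition(pen, npp - 1)[npp - 1]
            keep = np.nonzero(pen <= cutoff)[0]
            s, e, pen = s[keep], e[keep], pen[keep]
        order = np.lexsort((e, s, pen))[:npp]
        out = []
        for k in order:
            fs, re_ = int(s[k]), int(e[k])
            fl, rl = int(f_len[fs]), int(r_len[re_])
            out.append(
                EnginePair(
                    fwd_seq=window_seq[fs : fs + fl],
                    fwd_start=fs,
                    fwd_end=fs + fl,
                    rev_seq=revcomp(window_seq[re_ - rl : re_]),
                    rev_start=re_ - rl,
                    rev_end=re_,
                    penalty=float(pen[k]),
                )
            )
        return out
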