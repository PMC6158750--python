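"""Post-prediction confidence filters: MFE ratio and binomial p-value.

Hybridization free energy is computed by a pluggable backend.  The default
``builtin`` backend is a nearest-neighbor stack-energy model over
Watson-Crick and G:U stacks with fixed destabilizing penalties for
mismatches and bulges; its parameter table is versioned and shipped with the
package, so results are bit-reproducible everywhere.  When the ViennaRNA
python bindings are installed, the ``vienna`` backend delegates to
``RNA.duplexfold`` instead.

The MFE *ratio* of a prediction is its duplex energy divided by the energy
of the perfectly complementary site for the same sRNA, hence 1.0 for a
perfect site and smaller for weaker duplexes; predictions below a cutoff
(default 0.7) are discarded.

The p-value filter asks, per transcript: what is the chance that at least
one of the n candidate positions evaluated for this sRNA carries a degradome
signal of equal-or-better category purely by chance?  With q_c the fraction
of the transcript's signal positions at category <= c, that probability is
1 - (1 - q_c)^n.
"""

from __future__ import annotations

from .degradome import DegradationProfile
from .duplex import (
    STATE_MATCH,
    STATE_MISMATCH,
    STATE_SRNA_GAP,
    STATE_TARGET_GAP,
    STATE_WOBBLE,
    Column,
    DuplexAlignment,
)
from .encoding import complement

ENERGY_MODEL_VERSION = "builtin-nn-1.0"

# Nearest-neighbor stack free energies (kcal/mol, 37 C) indexed by the two
# consecutive pairs written as (sRNA base + partner base), RNA alphabet, with
# the sRNA strand read 5'->3'.  Watson-Crick/Watson-Crick entries follow the
# standard Turner-style values; stacks involving G:U pairs use milder,
# averaged stabilities.
_WC_STACK = {
    # keyed by the sRNA dinucleotide (both pairs Watson-Crick)
    "AA": -0.93, "AU": -1.10, "AC": -2.24, "AG": -2.08,
    "UA": -1.33, "UU": -0.93, "UC": -2.35, "UG": -2.11,
    "CA": -2.11, "CU": -2.08, "CC": -3.26, "CG": -2.36,
    "GA": -2.35, "GU": -2.24, "GC": -3.42, "GG": -3.26,
}
_GU_STACK_ENERGY = -1.20   # any stack with at least one G:U pair
_MISMATCH_PENALTY = 0.50   # destabilization per mismatched (unpaired) column
_GAP_PENALTY = 3.00        # destabilization per single-base bulge
_INITIATION = 4.09         # duplex initiation
_TERMINAL_AU_GU = 0.45     # per helix end closed by an A:U or G:U pair

_PAIRED = (STATE_MATCH, STATE_WOBBLE)


def _stack_energy(pair1: str, pair2: str) -> float:
    if pair1 in ("GU", "UG") or pair2 in ("GU", "UG"):
        return _GU_STACK_ENERGY
    return _WC_STACK[pair1[0] + pair2[0]]


def _rna(base: str) -> str:
    return "U" if base == "T" else base


def energy_from_columns(columns: tuple[Column, ...], srna: str, target: str,
                        window_based: bool = True) -> float:
    """Builtin nearest-neighbor energy of an aligned duplex.

    ``target`` is indexed by each column's window position when
    ``window_based`` (alignment columns), else positionwise by sRNA position.
    """
    pairs: list[str | None] = []
    for c in columns:
        if c.state in _PAIRED:
            s = _rna(srna[c.srna_pos - 1])
            if window_based:
                t = _rna(target[c.window_pos - 1])
            else:
                t = _rna(target[c.srna_pos - 1])
            pairs.append(s + t)
        else:
            pairs.append(None)
    energy = _INITIATION
    for p, q in zip(pairs, pairs[1:]):
        if p is not None and q is not None:
            energy += _stack_energy(p, q)
    for c in columns:
        if c.state == STATE_MISMATCH:
            energy += _MISMATCH_PENALTY
        elif c.state in (STATE_SRNA_GAP, STATE_TARGET_GAP):
            energy += _GAP_PENALTY
    paired = [p for p in pairs if p is not None]
    for terminal in (paired[0], paired[-1]) if paired else ():
        if terminal in ("AU", "UA", "GU", "UG"):
            energy += _TERMINAL_AU_GU
    return round(energy, 2)


def _positionwise_columns(srna: str, target: str) -> tuple[Column, ...]:
    """Gap-free columns for two equal-length strings paired index-by-index."""
    from .rules import MATCH, WOBBLE, classify_pair
    from .encoding import _SRNA_CODE

    if len(srna) != len(target):
        raise ValueError("sRNA and target must have equal length")
    cols = []
    for i, (s, t) in enumerate(zip(srna, target), start=1):
        kind = classify_pair(_SRNA_CODE[s], _SRNA_CODE[t] ^ 0b11)
        state = {MATCH: STATE_MATCH, WOBBLE: STATE_WOBBLE}.get(kind, STATE_MISMATCH)
        cols.append(Column(state, i, None))
    return tuple(cols)


def duplex_mfe(srna: str, target: str, backend: str = "builtin") -> float:
    """Hybridization free energy (kcal/mol) of a sRNA paired positionwise
    with a target excerpt of equal length (antiparallel, index i vs index i).
    """
    if backend == "builtin":
        return energy_from_columns(
            _positionwise_columns(srna, target), srna, target, window_based=False
        )
    if backend == "vienna":
        try:
            import RNA
        except ImportError as exc:
            raise RuntimeError("vienna backend requested but ViennaRNA "
                               "python bindings are not installed") from exc
        s = srna.replace("T", "U")
        # target arrives 3'->5' positionwise; RNA.duplexfold wants both 5'->3'
        t = target.replace("T", "U")[::-1]
        return round(RNA.duplexfold(s, t).energy, 2)
    raise ValueError(f"unknown energy backend {backend!r}")


def alignment_mfe(alignment: DuplexAlignment, backend: str = "builtin") -> float:
    """Energy of an accepted duplex alignment (gap columns included)."""
    if backend == "builtin":
        return energy_from_columns(
            alignment.columns, alignment.srna, alignment.target_window
        )
    target = "".join(
        alignment.target_window[c.window_pos - 1]
        for c in alignment.columns
        if c.window_pos is not None
    )
    # paired excerpt is already 3'->5' relative to the sRNA; duplex_mfe reverses
    return duplex_mfe(alignment.srna, target, backend=backend)


def perfect_site_mfe(srna: str, backend: str = "builtin") -> float:
    """Energy of the sRNA against its perfectly complementary target site."""
    return duplex_mfe(srna, complement(srna), backend=backend)


def mfe_ratio(alignment: DuplexAlignment, backend: str = "builtin") -> float:
    """MFE(predicted duplex) / MFE(perfect site); 1.0 for a perfect site."""
    perfect = perfect_site_mfe(alignment.srna, backend=backend)
    if perfect == 0:
        raise ValueError("degenerate sRNA: perfect-site MFE is zero")
    return alignment_mfe(alignment, backend=backend) / perfect


def site_pvalue(category: int, profile: DegradationProfile, n_evaluated: int) -> float:
    """Per-transcript binomial p-value of a cleavage signal.

    q_c = fraction of the transcript's signal positions with category <=
    ``category``; returns 1 - (1 - q_c) ** n_evaluated, the chance that at
    least one of the evaluated candidate positions reaches an
    equal-or-better category by chance.
    """
    if not profile.signals:
        raise ValueError("empty degradation profile")
    if n_evaluated < 1:
        raise ValueError("n_evaluated must be >= 1")
    total = len(profile.signals)
    as_good = sum(1 for s in profile.signals.values() if s.category <= category)
    q = as_good / total
    return 1.0 - (1.0 - q) ** n_evaluated
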