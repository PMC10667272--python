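"""The 1:1 Langmuir interaction model and its fitting variants.

Association phase (analyte at molar concentration ``C_i`` applied from
``t0_i`` to ``t_asso``)::

    R(t) = Rshift_i + Rmax_i * ka*C_i/(ka*C_i + kd) * (1 - exp(-(ka*C_i + kd)*(t - t0_i)))

Dissociation phase (buffer only, ``t >= t_asso``), in the amplitude-scaled
form used for fitting::

    R(t) = (Rmax_i + Rdrift_i) * ka*C_i/(ka*C_i + kd)
           * (1 - exp(-(ka*C_i + kd)*(t_asso - t0_i))) * exp(-kd*(t - t_asso))

An additive-drift dissociation form (``Rdrift_i + Rmax_i * ...``) is kept
for comparison as :func:`eval_dissociation_legacy`; the amplitude-scaled
form fits more stably because the drift term then decays with the signal
instead of persisting as a constant floor.

Variants
--------
* regenerative: ``t0_i`` is fixed to the known association start; for
  non-regenerative (single-cycle) titrations ``t0_i`` floats per cycle as
  the extrapolated time at which the response would have been zero, which
  absorbs the response accumulated over earlier cycles.
* global vs local Rmax: one shared saturation response, or one per cycle.
* bulk shift ``Rshift_i``: buffer-mismatch step present only during
  association.  Drift ``Rdrift_i``: rapid signal change at dissociation
  onset.  The two are mutually exclusive to avoid over-parameterization.

Rates are carried in log10 space inside the packed optimization vector so
positivity holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelVariant",
    "KineticsParams",
    "ModelError",
    "eval_association",
    "eval_dissociation",
    "eval_dissociation_legacy",
    "n_parameters",
    "pack_parameters",
    "unpack_parameters",
    "predict_cycle",
]

# lower bound multiplier for the floated t0_i: the extrapolated
# zero-response time cannot postdate the association start, and a loose
# lower bound of ten association lengths keeps the optimizer stable.
T0_LOWER_SPAN = 10.0


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelVariant:
    regenerative: bool = True
    global_rmax: bool = True
    bulk_shift: bool = False
    drift: bool = False

    def __post_init__(self) -> None:
        if self.bulk_shift and self.drift:
            raise ModelError(
                "bulk_shift and drift are mutually exclusive: the drift "
                "term is dropped when a bulk-shift term is included"
            )


@dataclass
class KineticsParams:
    """Full parameter vector for ``n`` fitted cycles.

    Per-cycle arrays always have length ``n``; when the variant does not
    float a term the corresponding entries are zeros (shift/drift) or the
    fixed schedule values (t0).
    """

    ka: float
    kd: float
    rmax: np.ndarray          # length n (identical entries under global Rmax)
    rshift: np.ndarray        # length n, zeros when bulk_shift off
    rdrift: np.ndarray        # length n, zeros when drift off
    t0: np.ndarray            # length n, absolute seconds
    variant: ModelVariant = field(default_factory=ModelVariant)

    def __post_init__(self) -> None:
        self.rmax = np.atleast_1d(np.asarray(self.rmax, dtype=float))
        self.rshift = np.atleast_1d(np.asarray(self.rshift, dtype=float))
        self.rdrift = np.atleast_1d(np.asarray(self.rdrift, dtype=float))
        self.t0 = np.atleast_1d(np.asarray(self.t0, dtype=float))
        n = self.t0.size
        if self.variant.global_rmax and self.rmax.size == 1:
            self.rmax = np.full(n, self.rmax[0])
        for name in ("rmax", "rshift", "rdrift"):
            arr = getattr(self, name)
            if arr.size != n:
                raise ModelError(
                    f"{name} has length {arr.size}, expected {n} (one per cycle)"
                )
        if not (np.isfinite(self.ka) and self.ka > 0):
            raise ModelError("ka must be finite and positive")
        if not (np.isfinite(self.kd) and self.kd > 0):
            raise ModelError("kd must be finite and positive")

    @property
    def n_cycles(self) -> int:
        return self.t0.size

    @property
    def kD(self) -> float:
        return self.kd / self.ka


def _kobs_occ(p: KineticsParams, conc: float) -> tuple[float, float]:
    kobs = p.ka * conc + p.kd
    if kobs <= 0:
        raise ModelError("degenerate rate: ka*C + kd must be positive")
    return kobs, p.ka * conc / kobs


def eval_association(p: KineticsParams, conc: float, t, i: int) -> np.ndarray:
    """Association-phase response at times ``t`` for cycle slot ``i``."""
    t = np.asarray(t, dtype=float)
    kobs, occ = _kobs_occ(p, conc)
    return p.rshift[i] + p.rmax[i] * occ * (1.0 - np.exp(-kobs * (t - p.t0[i])))


def eval_dissociation(p: KineticsParams, conc: float, t, i: int,
                      t_asso: float) -> np.ndarray:
    """Dissociation-phase response (amplitude-scaled drift form)."""
    t = np.asarray(t, dtype=float)
    kobs, occ = _kobs_occ(p, conc)
    amp = (p.rmax[i] + p.rdrift[i]) * occ * (
        1.0 - np.exp(-kobs * (t_asso - p.t0[i]))
    )
    return amp * np.exp(-p.kd * (t - t_asso))


def eval_dissociation_legacy(p: KineticsParams, conc: float, t, i: int,
                             t_asso: float) -> np.ndarray:
    """Additive-drift dissociation form, kept for comparison only.

    Identical to :func:`eval_dissociation` when ``Rdrift_i = 0``; differs
    in the long-time limit (drift persists here, decays there).
    """
    t = np.asarray(t, dtype=float)
    kobs, occ = _kobs_occ(p, conc)
    amp = p.rmax[i] * occ * (1.0 - np.exp(-kobs * (t_asso - p.t0[i])))
    return p.rdrift[i] + amp * np.exp(-p.kd * (t - t_asso))


# ---------------------------------------------------------------------------
# packing: bijection between KineticsParams and the flat optimizer vector

def n_parameters(variant: ModelVariant, n_cycles: int) -> int:
    """Free-parameter count: 2 rates + Rmax block + optional per-cycle blocks."""
    n = 2 + (1 if variant.global_rmax else n_cycles)
    if variant.bulk_shift:
        n += n_cycles
    if variant.drift:
        n += n_cycles
    if not variant.regenerative:
        n += n_cycles
    return n


def pack_parameters(p: KineticsParams) -> np.ndarray:
    """Flatten to the optimizer vector; rates go in as log10."""
    v = p.variant
    parts: list[np.ndarray] = [np.array([np.log10(p.ka), np.log10(p.kd)])]
    parts.append(p.rmax[:1] if v.global_rmax else p.rmax)
    if v.bulk_shift:
        parts.append(p.rshift)
    if v.drift:
        parts.append(p.rdrift)
    if not v.regenerative:
        parts.append(p.t0)
    return np.concatenate(parts)


def unpack_parameters(vector: np.ndarray, variant: ModelVariant,
                      n_cycles: int, t0_fixed: np.ndarray) -> KineticsParams:
    """Inverse of :func:`pack_parameters`.

    ``t0_fixed`` supplies the per-cycle association starts used when the
    variant is regenerative (t0 not floated).
    """
    vector = np.asarray(vector, dtype=float)
    expected = n_parameters(variant, n_cycles)
    if vector.size != expected:
        raise ModelError(
            f"parameter vector has length {vector.size}, expected {expected}"
        )
    pos = 2
    ka, kd = 10.0 ** vector[0], 10.0 ** vector[1]
    if variant.global_rmax:
        rmax = np.full(n_cycles, vector[pos])
        pos += 1
    else:
        rmax = vector[pos:pos + n_cycles].copy()
        pos += n_cycles
    rshift = np.zeros(n_cycles)
    rdrift = np.zeros(n_cycles)
    if variant.bulk_shift:
        rshift = vector[pos:pos + n_cycles].copy()
        pos += n_cycles
    if variant.drift:
        rdrift = vector[pos:pos + n_cycles].copy()
        pos += n_cycles
    if variant.regenerative:
        t0 = np.asarray(t0_fixed, dtype=float).copy()
    else:
        t0 = vector[pos:pos + n_cycles].copy()
    return KineticsParams(ka=ka, kd=kd, rmax=rmax, rshift=rshift,
                          rdrift=rdrift, t0=t0, variant=variant)


def predict_cycle(p: KineticsParams, i: int, conc: float, t_asso: float,
                  assoc_times: np.ndarray,
                  dissoc_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Model response over one cycle's association and dissociation windows."""
    return (
        eval_association(p, conc, assoc_times, i),
        eval_dissociation(p, conc, dissoc_times, i, t_asso),
    )
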