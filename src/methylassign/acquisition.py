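"""Acquisition arithmetic: NUS sparsity and coupling-transfer delays.

Non-uniform sampling schedules are specified by a nominal sparsity on the
acquired Nyquist grid. When the spectral width in each indirect dimension
is set wider than the signal range (oversampling), the grid holds more
hypercomplex points than a minimally sampled one with the same maximum
evolution times, and the *effective* sparsity relative to that minimal
grid is the nominal sparsity times the product of the per-dimension
oversampling factors (e.g. 0.55% with two-fold oversampling in three
dimensions -> 0.55% x 2^3 = 4.4%).

All APIs use fractions internally; percent formatting happens only at the
CLI boundary.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class NUSSpec:
    nominal_sparsity: float                 # fraction of the acquired grid
    n_indirect_dims: int
    oversampling_per_dim: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.nominal_sparsity <= 1.0):
            raise ValueError("nominal sparsity must lie in (0, 1]")
        if self.n_indirect_dims < 1:
            raise ValueError("need at least one indirect dimension")
        if any(f < 1.0 for f in self.oversampling_per_dim):
            raise ValueError("oversampling factors must be >= 1")


def effective_sparsity(spec: NUSSpec) -> tuple[float, float]:
    """(effective sparsity, per-dimension equivalent).

    effective = nominal x product(oversampling factors);
    per-dimension equivalent = effective ** (1 / n_indirect_dims).
    """
    eff = spec.nominal_sparsity
    for f in spec.oversampling_per_dim:
        eff *= f
    return eff, eff ** (1.0 / spec.n_indirect_dims)


def transfer_delay(j_coupling_hz: float, kind: str = "half") -> float:
    """INEPT/COSY transfer delay in seconds for a scalar coupling J.

    ``half`` -> 1/(2J) (e.g. ~4 ms for the 125-Hz one-bond CH coupling);
    ``full`` -> 1/J (e.g. ~28.6 ms constant-time period for J_CC = 35 Hz).
    """
    if j_coupling_hz <= 0:
        raise ValueError("J must be positive")
    if kind == "half":
        return 1.0 / (2.0 * j_coupling_hz)
    if kind == "full":
        return 1.0 / j_coupling_hz
    raise ValueError(f"unknown delay kind {kind!r}")
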