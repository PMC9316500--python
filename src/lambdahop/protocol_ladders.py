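"""Per-replica scaling schedules for the four enhanced-sampling protocols.

Four ladder flavours are supported:

* ``t-REM``    — gas phase (lam = 0), geometric intramolecular scaling.
* ``ST-HREM``  — solution (lam = 1), geometric intramolecular scaling;
  only the solute term is tempered, the solvent stays cold.
* ``lambda-hop`` — pure alchemical ladder: s_intra = 1 everywhere, the
  solute-solvent coupling descends geometrically from 1 to lambda_min.
* ``FEP+``     — the lambda-hop ladder augmented with a "hot zone":
  an intramolecular scaling equal to 1 at both end states and minimal
  (S_min) at the centre of the stratification.

The geometric rule is  s_m = S**((m-1)/(N_rep-1)), m = 1..N_rep, so slot 1
is always the target state.  The FEP+ hot-zone profile reuses the geometric
rule on each half of the ladder (a symmetric tent in log space), since only
its endpoints and centre value are prescribed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .errors import ProtocolError

PROTOCOLS = ("t-REM", "ST-HREM", "lambda-hop", "FEP+")


@dataclass(frozen=True)
class LadderPoint:
    """One replica slot: 1-based index, intramolecular scaling, coupling scaling."""

    m: int
    s_intra: float
    lam: float

    def __post_init__(self) -> None:
        if not (0.0 < self.s_intra <= 1.0):
            raise ProtocolError(f"s_intra must be in (0, 1], got {self.s_intra}")
        if not (0.0 <= self.lam <= 1.0):
            raise ProtocolError(f"lambda must be in [0, 1], got {self.lam}")


@dataclass(frozen=True)
class Ladder:
    """Ordered scaling schedule; slot 1 is the target state."""

    protocol: str
    points: tuple[LadderPoint, ...]
    S_min: float = 1.0
    lambda_min: float = 1.0

    @property
    def n_rep(self) -> int:
        return len(self.points)

    @property
    def s_intra(self) -> np.ndarray:
        return np.array([p.s_intra for p in self.points])

    @property
    def lam(self) -> np.ndarray:
        return np.array([p.lam for p in self.points])

    def __iter__(self) -> Iterator[LadderPoint]:
        return iter(self.points)

    def to_text(self, T0: float = 300.0) -> str:
        """Delimited-text table with columns (m, s_intra, lambda, T_eff)."""
        buf = io.StringIO()
        buf.write(f"# protocol={self.protocol} nrep={self.n_rep} "
                  f"smin={self.S_min!r} lmin={self.lambda_min!r}\n")
        buf.write("m\ts_intra\tlambda\tT_eff\n")
        for p in self.points:
            buf.write(f"{p.m}\t{p.s_intra!r}\t{p.lam!r}\t"
                      f"{effective_temperature(p.s_intra, T0)!r}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "Ladder":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].lstrip("# ").split()
        meta = dict(item.split("=", 1) for item in header)
        pts = []
        for ln in lines[2:]:
            m, s, lam, _ = ln.split("\t")
            pts.append(LadderPoint(int(m), float(s), float(lam)))
        return cls(protocol=meta["protocol"], points=tuple(pts),
                   S_min=float(meta["smin"]), lambda_min=float(meta["lmin"]))


def build_geometric_ladder(S_min: float, N_rep: int) -> np.ndarray:
    """Geometric scaling factors s_m = S_min**((m-1)/(N_rep-1))."""
    if not (0.0 < S_min <= 1.0):
        raise ProtocolError(f"S_min must be in (0, 1], got {S_min}")
    if N_rep < 2:
        raise ProtocolError(f"N_rep must be >= 2, got {N_rep}")
    m = np.arange(N_rep)
    return S_min ** (m / (N_rep - 1))


def build_trem_ladder(S_min: float, N_rep: int) -> Ladder:
    """Gas-phase tempering ladder: lam = 0, geometric s_intra."""
    s = build_geometric_ladder(S_min, N_rep)
    pts = tuple(LadderPoint(i + 1, float(si), 0.0) for i, si in enumerate(s))
    return Ladder("t-REM", pts, S_min=S_min, lambda_min=1.0)


def build_sthrem_ladder(S_min: float, N_rep: int) -> Ladder:
    """Solute-tempering ladder in solution: lam = 1, geometric s_intra."""
    s = build_geometric_ladder(S_min, N_rep)
    pts = tuple(LadderPoint(i + 1, float(si), 1.0) for i, si in enumerate(s))
    return Ladder("ST-HREM", pts, S_min=S_min, lambda_min=1.0)


def build_lambda_hop_ladder(lambda_min: float, N_rep: int) -> Ladder:
    """Pure alchemical ladder: s_intra = 1, lam descends geometrically."""
    lam = build_geometric_ladder(lambda_min, N_rep)
    pts = tuple(LadderPoint(i + 1, 1.0, float(li)) for i, li in enumerate(lam))
    return Ladder("lambda-hop", pts, S_min=1.0, lambda_min=lambda_min)


def feplus_hot_zone_profile(S_min: float, N_rep: int) -> np.ndarray:
    """Symmetric hot-zone profile: s = 1 at both ends, S_min at the centre.

    s_m = S_min**(1 - |m - c| / (c - 1)) with c = (N_rep + 1)/2; a tent in
    log space, symmetric under m -> N_rep + 1 - m.  For even N_rep the two
    central slots share the near-minimum value.
    """
    if not (0.0 < S_min <= 1.0):
        raise ProtocolError(f"S_min must be in (0, 1], got {S_min}")
    if N_rep < 3:
        raise ProtocolError("FEP+ ladder needs N_rep >= 3 (no interior point)")
    m = np.arange(1, N_rep + 1, dtype=float)
    c = 0.5 * (N_rep + 1)
    return S_min ** (1.0 - np.abs(m - c) / (c - 1.0))


def build_feplus_ladder(lambda_min: float, S_min: float, N_rep: int) -> Ladder:
    """FEP+ ladder: geometric lam plus the symmetric hot-zone s profile."""
    lam = build_geometric_ladder(lambda_min, N_rep)
    s = feplus_hot_zone_profile(S_min, N_rep)
    pts = tuple(LadderPoint(i + 1, float(s[i]), float(lam[i])) for i in range(N_rep))
    return Ladder("FEP+", pts, S_min=S_min, lambda_min=lambda_min)


def build_ladder(protocol: str, N_rep: int, S_min: float = 1.0,
                 lambda_min: float = 0.05) -> Ladder:
    """Dispatch on protocol name."""
    if protocol == "t-REM":
        return build_trem_ladder(S_min, N_rep)
    if protocol == "ST-HREM":
        return build_sthrem_ladder(S_min, N_rep)
    if protocol == "lambda-hop":
        return build_lambda_hop_ladder(lambda_min, N_rep)
    if protocol == "FEP+":
        return build_feplus_ladder(lambda_min, S_min, N_rep)
    raise ProtocolError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")


def effective_temperature(s: float, T0: float = 300.0) -> float:
    """Map a scaling factor to the equivalent temperature T0 / s."""
    if not s > 0:
        raise ProtocolError(f"scaling factor must be positive, got {s}")
    if not T0 > 0:
        raise ProtocolError(f"T0 must be positive, got {T0}")
    return T0 / s
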