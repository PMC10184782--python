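"""Historical effective population size from PSMC-format output.

PSMC emits, per EM iteration, a scaled mutation parameter theta_0 (``TR``
line) and a piecewise-constant relative-size function given as atomic
intervals ``RS k t_k lambda_k`` with time in units of 2*N0 generations.
This module parses the final iteration, rescales it to years and diploid
individuals using a per-species generation time g (years) and mutation
rate mu (per site per generation):

    N0        = theta_0 / (4 * mu * s)        (s = sites per input bin)
    Ne_k      = lambda_k * N0
    t_k_years = 2 * N0 * t_k * g

and summarizes the trajectory as a duration-weighted harmonic mean over
epochs older than a cutoff (default 10 kya), the drift-relevant average.
The ratio of that harmonic mean to a census size Nc = density * area
flags species whose contemporary population is small relative to their
deep history.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EmptySupportError,
    InvalidParameterError,
    MalformedInputError,
)

DEFAULT_BIN_SIZE = 100
DEFAULT_MIN_AGE_YEARS = 10_000.0


@dataclass(frozen=True)
class PsmcRecord:
    """Final-iteration parameters of a PSMC run.

    ``times`` are interval left endpoints in units of 2*N0 generations
    (strictly increasing from 0); ``lambdas`` are relative sizes; the last
    interval is open-ended toward the past.
    """

    theta0: float
    times: np.ndarray
    lambdas: np.ndarray
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        lam = np.asarray(self.lambdas, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "lambdas", lam)
        if self.theta0 <= 0:
            raise InvalidParameterError(f"theta0 must be > 0, got {self.theta0}")
        if self.bin_size < 1:
            raise InvalidParameterError(f"bin_size must be >= 1, got {self.bin_size}")
        if t.size == 0 or t.size != lam.size:
            raise InvalidParameterError("times and lambdas must be nonempty, equal length")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise InvalidParameterError("times must strictly increase from 0")
        if np.any(lam <= 0):
            raise InvalidParameterError("all lambda_k must be > 0")


@dataclass(frozen=True)
class Epoch:
    start_years: float
    end_years: float
    ne: float


@dataclass(frozen=True)
class NeTrajectory:
    """Piecewise-constant Ne history in years before present.

    Epochs are contiguous, ordered young to old; the open-ended oldest
    PSMC interval is not retained (no epoch has infinite end).
    """

    epochs: tuple[Epoch, ...]
    gen_time: float
    mu: float

    def __post_init__(self) -> None:
        if not self.epochs:
            raise InvalidParameterError("trajectory must have at least one epoch")
        prev_end = None
        for ep in self.epochs:
            if not (ep.start_years < ep.end_years):
                raise InvalidParameterError(f"epoch start {ep.start_years} >= end {ep.end_years}")
            if ep.ne <= 0:
                raise InvalidParameterError(f"epoch Ne must be > 0, got {ep.ne}")
            if prev_end is not None and not np.isclose(ep.start_years, prev_end):
                raise InvalidParameterError("epochs must be contiguous")
            prev_end = ep.end_years

    def ne_at(self, age_years: float) -> float:
        """Ne at a given age (years before present)."""
        for ep in self.epochs:
            if ep.start_years <= age_years < ep.end_years:
                return ep.ne
        raise EmptySupportError(f"age {age_years} outside trajectory support")


@dataclass(frozen=True)
class CensusRecord:
    """Contemporary census size as density (individuals/km^2) x area (km^2)."""

    density: float
    area: float

    def __post_init__(self) -> None:
        if self.density <= 0 or self.area <= 0:
            raise InvalidParameterError(
                f"density and area must be > 0, got density={self.density}, area={self.area}"
            )

    @property
    def nc(self) -> float:
        return self.density * self.area


def parse_psmc(text: str, bin_size: int = DEFAULT_BIN_SIZE) -> PsmcRecord:
    """Parse PSMC-format text, returning the FINAL iteration's parameters.

    Iteration blocks are separated by ``//`` lines; within a block the
    ``TR`` line carries theta_0 (and rho, ignored) and ``RS`` lines carry
    ``k t_k lambda_k ...``. Earlier iterations are ignored.

    Raises
    ------
    MalformedInputError
        If no complete block with both TR and RS lines exists; the message
        names the first offending line number.
    """
    lines = text.splitlines()
    # collect (line_number, line) per block
    blocks: list[list[tuple[int, str]]] = [[]]
    for i, line in enumerate(lines, start=1):
        if line.startswith("//"):
            blocks.append([])
        else:
            blocks[-1].append((i, line))
    # last block containing a TR line wins
    for block in reversed(blocks):
        tr = [(i, l) for i, l in block if l.startswith("TR")]
        rs = [(i, l) for i, l in block if l.startswith("RS")]
        if not tr and not rs:
            continue
        if not tr:
            raise MalformedInputError(
                f"block with RS but no TR line (first RS at line {rs[0][0]})"
            )
        if not rs:
            raise MalformedInputError(
                f"block with TR but no RS line (TR at line {tr[0][0]})"
            )
        try:
            theta0 = float(tr[-1][1].split()[1])
        except (IndexError, ValueError) as exc:
            raise MalformedInputError(f"unparseable TR line at line {tr[-1][0]}") from exc
        times, lambdas = [], []
        for i, l in rs:
            parts = l.split()
            try:
                times.append(float(parts[2]))
                lambdas.append(float(parts[3]))
            except (IndexError, ValueError) as exc:
                raise MalformedInputError(f"unparseable RS line at line {i}") from exc
        return PsmcRecord(theta0=theta0, times=np.array(times), lambdas=np.array(lambdas), bin_size=bin_size)
    raise MalformedInputError("no TR/RS lines found in any block (line 1)")


def rescale_trajectory(rec: PsmcRecord, mu: float, gen_time: float) -> NeTrajectory:
    """Rescale a PSMC record to years and diploid individuals.

    N0 = theta0/(4*mu*s); Ne_k = lambda_k*N0; t_k(years) = 2*N0*t_k*g.
    Epochs are built from consecutive time points; the open-ended last
    interval is dropped (its Ne has unbounded temporal support).
    """
    if mu <= 0:
        raise InvalidParameterError(f"mu must be > 0, got {mu}")
    if gen_time <= 0:
        raise InvalidParameterError(f"gen_time must be > 0, got {gen_time}")
    n0 = rec.theta0 / (4.0 * mu * rec.bin_size)
    times_years = 2.0 * n0 * rec.times * gen_time
    ne = rec.lambdas * n0
    if rec.times.size < 2:
        raise MalformedInputError("need at least 2 RS time points to form an epoch")
    epochs = tuple(
        Epoch(start_years=float(times_years[k]), end_years=float(times_years[k + 1]), ne=float(ne[k]))
        for k in range(rec.times.size - 1)
    )
    return NeTrajectory(epochs=epochs, gen_time=gen_time, mu=mu)


def harmonic_mean_ne(
    traj: NeTrajectory,
    min_age_years: float = DEFAULT_MIN_AGE_YEARS,
    weighted: bool = True,
) -> float:
    """Harmonic mean Ne over the trajectory portion older than ``min_age_years``.

    Duration-weighted by default: H = (sum w_i) / (sum w_i/Ne_i) with w_i the
    years of epoch i older than the cutoff. ``weighted=False`` gives the
    unweighted mean over contributing epochs, for comparison with analyses
    that average the atomic intervals directly.
    """
    weights, nes = [], []
    for ep in traj.epochs:
        overlap = ep.end_years - max(ep.start_years, min_age_years)
        if overlap > 0:
            weights.append(overlap)
            nes.append(ep.ne)
    if not weights:
        raise EmptySupportError(
            f"no epoch portion older than {min_age_years} years in trajectory"
        )
    w = np.asarray(weights, dtype=float)
    ne = np.asarray(nes, dtype=float)
    if not weighted:
        w = np.ones_like(w)
    return float(w.sum() / (w / ne).sum())


def ne_nc_ratio(ne_harm: float, census: CensusRecord) -> float:
    """Ratio of deep historical Ne to contemporary census size Nc."""
    if ne_harm <= 0:
        raise InvalidParameterError(f"ne_harm must be > 0, got {ne_harm}")
    return ne_harm / census.nc


def trajectory_to_tsv(traj: NeTrajectory) -> str:
    """Serialize a trajectory as TSV (start_years, end_years, Ne)."""
    out = ["start_years\tend_years\tne"]
    for ep in traj.epochs:
        out.append(f"{ep.start_years:.10g}\t{ep.end_years:.10g}\t{ep.ne:.10g}")
    return "\n".join(out) + "\n"
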