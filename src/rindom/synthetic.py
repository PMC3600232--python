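"""Generate multi-domain pseudo-protein structures with known domain labels.

The community-division pipeline only consumes pairwise distances, so these
generators emulate the one property that matters: residue contacts are dense
inside a domain and sparse between domains.  Each domain is a self-avoiding
Ca walk with a fixed ~3.8 A step confined to a compact sphere; consecutive
domains sit at a fixed center-to-center separation along the x axis and are
joined by a linker whose residues follow a circular arc with exact Ca steps
(so the chain geometry stays valid while the endpoints are pinned).  Every
residue also gets a configurable number of pseudo side-chain heavy atoms
within 2.5 A of its Ca so that the centroid and any-atom vertex strategies
are exercised, not just Ca.

Domains are random coils, not folds: there is no secondary structure, no
Ramachandran statistics and no rotamers.  Linker residues are labelled as
no-domain, matching the evaluation's denominator rule.
Generation is fully reproducible from the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .evaluate import Domain, DomainAnnotation
from .structure_io import Atom, Residue, StructureModel

logger = logging.getLogger(__name__)

#: Minimum allowed distance between non-consecutive Ca atoms (self-avoidance).
MIN_NONADJACENT_CA = 3.0
#: Pseudo side-chain atoms are placed uniformly within this radius of the Ca.
SIDECHAIN_RADIUS = 2.5

_SIDECHAIN_NAMES = ["CB", "CG", "CD", "CE", "CZ", "CH", "CK", "CL"]


class GenerationError(RuntimeError):
    """The requested geometry could not be packed within bounded retries."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic multi-domain chain.

    ``domain_separation`` is the center-to-center distance between
    consecutive domain spheres; it must exceed twice the domain radius
    (about ``3 * residues_per_domain**(1/3)`` A) so that inter-domain Ca
    contacts at the cutoff scales in use (<= 10 A) are rare.
    """

    n_domains: int = 2
    residues_per_domain: int = 60
    linker_length: int = 6
    domain_separation: float = 40.0
    ca_step: float = 3.8
    sidechain_atoms_per_residue: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")
        if self.residues_per_domain < 2:
            raise ValueError("residues_per_domain must be >= 2")
        if self.linker_length < 0 or self.sidechain_atoms_per_residue < 0:
            raise ValueError("linker_length and sidechain count must be >= 0")
        if not self.ca_step > 0:
            raise ValueError("ca_step must be > 0")
        if self.n_domains > 1:
            if not self.domain_separation > 2.0 * self.domain_radius:
                raise ValueError(
                    f"domain_separation {self.domain_separation} must exceed twice "
                    f"the domain radius ({self.domain_radius:.2f} A)"
                )
            # the linker must be able to span the inter-sphere gap
            gap = self.domain_separation - 2.0 * self.domain_radius
            if self.linker_length * self.ca_step < gap:
                raise ValueError(
                    f"linker of {self.linker_length} residues (span "
                    f"{self.linker_length * self.ca_step:.1f} A) cannot bridge "
                    f"the {gap:.1f} A gap between domain spheres"
                )

    @property
    def domain_radius(self) -> float:
        """Confinement sphere radius, ~3 * N^(1/3) A (compact globule)."""
        return 3.0 * self.residues_per_domain ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# Geometry helpers


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _clashes(p: np.ndarray, placed: list[np.ndarray], skip_last: bool) -> bool:
    """True if p comes within MIN_NONADJACENT_CA of any non-consecutive Ca."""
    upto = len(placed) - 1 if skip_last else len(placed)
    for q in placed[:upto]:
        if np.linalg.norm(p - q) < MIN_NONADJACENT_CA:
            return True
    return False


def _confined_walk(
    rng: np.random.Generator,
    start: np.ndarray,
    center: np.ndarray,
    radius: float,
    n_residues: int,
    placed: list[np.ndarray],
    step: float,
    steer_anchor: np.ndarray | None = None,
    steer_last: int = 8,
    step_tries: int = 200,
) -> list[np.ndarray] | None:
    """Self-avoiding walk of *n_residues* points confined to a sphere.

    The walk starts at *start* (already placed by the caller).  When
    *steer_anchor* is given, the last *steer_last* steps are biased toward it
    so the walk ends where the following linker can take over.  Returns
    ``None`` on failure so the caller can retry with fresh randomness.
    """
    points = [start.copy()]
    for i in range(n_residues - 1):
        remaining = n_residues - 2 - i  # steps still to place after this one
        prev = points[-1]
        for _ in range(step_tries):
            u = _random_unit(rng)
            if steer_anchor is not None and remaining < steer_last:
                pull = steer_anchor - prev
                nrm = float(np.linalg.norm(pull))
                if nrm > 1e-9:
                    u = u + 1.2 * (steer_last - remaining) / steer_last * pull / nrm
                    u = u / np.linalg.norm(u)
            p = prev + step * u
            if np.linalg.norm(p - center) > radius:
                continue
            if _clashes(p, placed + points, skip_last=True):
                continue
            points.append(p)
            break
        else:
            return None
    return points


def _arc_linker(
    rng: np.random.Generator,
    start: np.ndarray,
    end: np.ndarray,
    n_inner: int,
    step: float,
    placed: list[np.ndarray],
    tries: int = 40,
) -> list[np.ndarray] | None:
    """Points strictly between *start* and *end* along a circular arc whose
    chords all have length *step* (n_inner + 1 equal steps in total)."""
    d = float(np.linalg.norm(end - start))
    n_steps = n_inner + 1
    if d > n_steps * step * (1.0 - 1e-9):
        return None  # cannot reach even with a straight linker
    if n_inner == 0:
        return [] if abs(d - step) < 0.05 else None

    # solve sin(n*alpha/2) / sin(alpha/2) = d / step for the step angle alpha
    ratio = d / step

    def f(alpha: float) -> float:
        return math.sin(n_steps * alpha / 2.0) / math.sin(alpha / 2.0) - ratio

    lo, hi = 1e-9, 2.0 * math.pi / n_steps - 1e-9
    if f(lo) < 0:
        return None
    alpha = brentq(f, lo, hi, xtol=1e-12)
    rho = step / (2.0 * math.sin(alpha / 2.0))

    u = (end - start) / d
    for _ in range(tries):
        # random arc plane containing the chord
        w = _random_unit(rng)
        w = w - np.dot(w, u) * u
        norm = np.linalg.norm(w)
        if norm < 1e-6:
            continue
        w = w / norm
        mid = 0.5 * (start + end)
        h = math.sqrt(max(rho * rho - 0.25 * d * d, 0.0))
        center = mid - h * w
        # angular positions of the endpoints in the (u, w) plane
        a0 = math.atan2(float(np.dot(start - center, w)),
                        float(np.dot(start - center, u)))
        a1 = math.atan2(float(np.dot(end - center, w)),
                        float(np.dot(end - center, u)))
        span = (a1 - a0) % (2.0 * math.pi)
        delta = span / n_steps if abs(span - n_steps * alpha) < abs(
            (span - 2.0 * math.pi) - (-n_steps * alpha)
        ) else (span - 2.0 * math.pi) / n_steps
        pts = [
            center
            + rho * math.cos(a0 + i * delta) * u
            + rho * math.sin(a0 + i * delta) * w
            for i in range(1, n_steps)
        ]
        steps = np.linalg.norm(
            np.diff(np.array([start] + pts + [end]), axis=0), axis=1
        )
        if np.any(np.abs(steps - step) > 0.05):
            continue
        if any(_clashes(p, placed, skip_last=True) for p in pts):
            continue
        return pts
    return None


# ---------------------------------------------------------------------------
# Generation


def generate(spec: SyntheticSpec) -> tuple[StructureModel, DomainAnnotation]:
    """Generate one synthetic chain and its ground-truth domain annotation.

    Returns a :class:`StructureModel` (single chain ``A``, residues numbered
    from 1) and the matching :class:`DomainAnnotation` labelling exactly the
    domain (non-linker) residues.  Byte-identical output for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    radius = spec.domain_radius
    step = spec.ca_step
    max_span = (spec.linker_length + 1) * step
    restarts = 80

    for attempt in range(restarts):
        coords: list[np.ndarray] = []
        domain_slices: list[tuple[int, int]] = []  # [start, end) residue index
        ok = True
        entry = np.zeros(3)
        for d in range(spec.n_domains):
            center = np.array([d * spec.domain_separation, 0.0, 0.0])
            start = (
                center + np.array([-0.5 * radius, 0.0, 0.0]) if d == 0 else entry
            )
            if d < spec.n_domains - 1:
                # entry point on the next sphere's near surface, and an anchor
                # near this sphere's far surface the walk is steered toward
                direction = np.array(
                    [-1.0, rng.uniform(-0.15, 0.15), rng.uniform(-0.15, 0.15)]
                )
                direction /= np.linalg.norm(direction)
                next_entry = (
                    center + np.array([spec.domain_separation, 0.0, 0.0])
                    + (radius - 0.3) * direction
                )
                anchor = center + np.array([radius - 1.0, 0.0, 0.0])
            else:
                next_entry = anchor = None
            walk = _confined_walk(
                rng, start, center, radius, spec.residues_per_domain, coords,
                step, steer_anchor=anchor,
            )
            if walk is None:
                ok = False
                break
            domain_slices.append((len(coords), len(coords) + len(walk)))
            coords.extend(walk)
            if next_entry is not None:
                reach = float(np.linalg.norm(next_entry - coords[-1]))
                if not 2.0 * step <= reach <= 0.995 * max_span:
                    ok = False
                    break
                linker = _arc_linker(
                    rng, coords[-1], next_entry, spec.linker_length, step, coords
                )
                if linker is None:
                    ok = False
                    break
                coords.extend(linker)
                entry = next_entry
        if ok:
            break
    else:
        raise GenerationError(
            f"could not pack {spec.n_domains} domains after {restarts} restarts "
            f"(seed {spec.seed}); try a longer linker or larger separation"
        )
    if attempt:
        logger.info("generation succeeded after %d restart(s)", attempt)

    structure_id = f"SYN{spec.n_domains}D{spec.seed:05d}"
    residues: list[Residue] = []
    for i, ca in enumerate(coords):
        atoms = [Atom("CA", "C", ca)]
        for s in range(spec.sidechain_atoms_per_residue):
            offset = SIDECHAIN_RADIUS * rng.uniform() ** (1.0 / 3.0)
            atoms.append(
                Atom(_SIDECHAIN_NAMES[s % len(_SIDECHAIN_NAMES)], "C",
                     ca + offset * _random_unit(rng))
            )
        residues.append(Residue("A", i + 1, "", "ALA", atoms))
    model = StructureModel(structure_id, {"A": residues})

    domains = [
        Domain(f"d{k + 1}", [("A", lo + 1, "", hi, "")])
        for k, (lo, hi) in enumerate(domain_slices)
    ]
    annotation = DomainAnnotation(structure_id, domains)
    return model, annotation
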