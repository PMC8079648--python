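"""Synthetic bilateral modular test systems and exact samplers.

The study system is a subcortical-limbic-like network: two mirrored
hemispheres of homologous regions, each split into a limbic and a
striatal-thalamic module, plus a midline brainstem-like node coupled to
both hemispheres.  Interactions are positive within modules and across
homologous pairs, sparsely negative between modules, and every region
carries a mildly negative baseline sensitivity, which together produce
an energy landscape with a handful of dominant attractors (all-inactive
plus module-wise activation patterns).

The exact parameter values of the original subcortical system are not
published as numbers, so the generator's default scales (intra-module
J ~ 0.3, homotopic J ~ 0.4, cross-module J ~ -0.15, H ~ -0.3) are a
calibration chosen so that the emitted landscape has few dominant,
hemisphere-symmetric attractors; they are conventions of this package,
not measured quantities.

"Diseased" variants are produced by adding Gaussian noise ~N(0, 0.1) to
every parameter, and callosotomy-style variants by strengthening the
interhemispheric couplings according to their polarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import BinaryRecording
from .landscape import assign_basins
from .mem import state_matrix, state_table
from .params import SystemParams

__all__ = [
    "SyntheticSpec",
    "REGION_NAMES",
    "make_bilateral_system",
    "perturb_system",
    "strengthen_interhemispheric",
    "sample_states",
    "random_system",
]

#: Homologous region names per hemisphere (limbic module first three,
#: striatal-thalamic module the remaining four).
REGION_NAMES = ("HIPP", "AMYG", "NACC", "CAU", "PUT", "PAL", "THL")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one bilateral modular system.

    ``intra_module_j``/``homotopic_j``/``inter_module_j`` scale the
    within-module, homologous-pair and between-module couplings;
    ``jitter_sd`` adds structural heterogeneity at generation time
    (mirrored across hemispheres when ``symmetry``).  ``noise_sd`` is
    the default scale for the diseased-variant perturbation, not used
    by the generator itself.
    """

    n_per_hemi: int = 7
    include_midline: bool = True
    intra_module_j: float = 0.3
    homotopic_j: float = 0.4
    inter_module_j: float = -0.15
    midline_j: float = 0.2
    h_base: float = -0.3
    jitter_sd: float = 0.05
    symmetry: bool = True
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_hemi < 1:
            raise ValueError("n_per_hemi must be >= 1")
        if self.noise_sd < 0 or self.jitter_sd < 0:
            raise ValueError("noise scales must be >= 0")

    @property
    def n_regions(self) -> int:
        return 2 * self.n_per_hemi + (1 if self.include_midline else 0)


def _region_labels(spec: SyntheticSpec) -> tuple[str, ...]:
    if spec.n_per_hemi == len(REGION_NAMES):
        base = REGION_NAMES
    else:
        base = tuple(f"N{i}" for i in range(spec.n_per_hemi))
    labels = [f"L {b}" for b in base] + [f"R {b}" for b in base]
    if spec.include_midline:
        labels.append("BSTEM")
    return tuple(labels)


def _module_of(i: int, n_per_hemi: int) -> int:
    """0 = limbic-like module, 1 = striatal-thalamic-like module."""
    return 0 if (i % n_per_hemi) < max(1, n_per_hemi // 2) else 1


def _draw_system(spec: SyntheticSpec, rng: np.random.Generator) -> SystemParams:
    nh = spec.n_per_hemi
    n = spec.n_regions
    mid = n - 1 if spec.include_midline else None

    def swap(i: int) -> int:
        if i == mid:
            return i
        return i + nh if i < nh else i - nh

    h = np.empty(n)
    for i in range(nh):
        v = spec.h_base + spec.jitter_sd * rng.normal()
        h[i] = v
        h[i + nh] = v if spec.symmetry else (
            spec.h_base + spec.jitter_sd * rng.normal()
        )
    if mid is not None:
        h[mid] = spec.h_base + spec.jitter_sd * rng.normal()

    j = np.zeros((n, n))
    done: set[tuple[int, int]] = set()
    for i in range(n):
        for k in range(i + 1, n):
            if (i, k) in done:
                continue
            v = _draw_edge(spec, rng, i, k, nh, mid)
            pairs = [(i, k)]
            if spec.symmetry:
                si, sk = sorted((swap(i), swap(k)))
                if (si, sk) != (i, k):
                    pairs.append((si, sk))
            for a, b in pairs:
                j[a, b] = j[b, a] = v
                done.add((a, b))
    return SystemParams(h=h, j=j, region_labels=_region_labels(spec))


def _draw_edge(spec, rng, i, k, nh, mid) -> float:
    jit = spec.jitter_sd * rng.normal()
    if mid is not None and (i == mid or k == mid):
        # brainstem-like node: positive coupling to about half the regions
        return spec.midline_j + jit if rng.random() < 0.5 else 0.0
    same_hemi = (i < nh) == (k < nh)
    homotopic = abs(i - k) == nh
    same_module = _module_of(i, nh) == _module_of(k, nh)
    if homotopic:
        return spec.homotopic_j + jit
    if same_module:
        if same_hemi:
            return spec.intra_module_j + jit
        # same module, other hemisphere: weaker positive, sparse
        return 0.5 * spec.intra_module_j + jit if rng.random() < 0.5 else 0.0
    # different modules: sparse, typically negative
    p = 0.5 if same_hemi else 0.25
    return spec.inter_module_j + jit if rng.random() < p else 0.0


def make_bilateral_system(spec: SyntheticSpec = SyntheticSpec()) -> SystemParams:
    """Generate a bilateral modular system with a multistable landscape.

    Deterministic given ``spec.seed``.  The emitted system is required
    to have at least 2 strict local minima with the top-5 attractors
    covering more than half of the probability mass; draws failing the
    check are rejected and redrawn (up to 20 attempts) so every emitted
    system has the attractor structure the study design assumes.
    """
    last_err = None
    for attempt in range(20):
        rng = np.random.default_rng((spec.seed, attempt))
        params = _draw_system(spec, rng)
        try:
            ls = assign_basins(params)
        except ValueError as err:
            last_err = err
            continue
        top5 = sum(ls.ocr[m] for m in ls.minima[:5])
        if len(ls.minima) >= 2 and top5 > 0.5:
            return params
        last_err = ValueError(
            f"{len(ls.minima)} minima, top-5 OCR {top5:.3f}"
        )
    raise ValueError(
        "could not generate a multistable bilateral system in 20 attempts "
        f"(last: {last_err}); adjust the J/H scales"
    )


def perturb_system(
    base: SystemParams, sd: float = 0.1, seed: int = 0
) -> SystemParams:
    """Gaussian-perturbed ("diseased") variant of a system.

    Adds i.i.d. N(0, sd) noise to every H and every upper-triangle J
    entry, mirrored to the lower triangle so J stays symmetric; the
    diagonal stays zero.
    """
    rng = np.random.default_rng(seed)
    h, j = base.copy_arrays()
    h += rng.normal(0.0, sd, size=h.shape)
    iu = np.triu_indices(base.n_regions, k=1)
    j[iu] += rng.normal(0.0, sd, size=iu[0].size)
    j.T[iu] = j[iu]
    return base.replace(h=h, j=j)


def strengthen_interhemispheric(
    base: SystemParams,
    left: tuple[int, ...],
    right: tuple[int, ...],
    sd: float = 0.1,
    seed: int = 0,
) -> SystemParams:
    """Polarity-preserving boost of every left-right coupling.

    Each nonzero interhemispheric J_ij gains |g|*sign(J_ij) with
    g ~ N(0, sd): positive couplings get stronger, negative ones more
    negative, zero couplings stay zero.  All other parameters are
    untouched.  Emulates an abnormally interconnected (epileptogenic)
    variant ahead of a virtual callosotomy.
    """
    rng = np.random.default_rng(seed)
    h, j = base.copy_arrays()
    for l in left:
        for r in right:
            g = rng.normal(0.0, sd)
            if j[l, r] != 0.0:
                j[l, r] += abs(g) * np.sign(j[l, r])
                j[r, l] = j[l, r]
    return base.replace(h=h, j=j)


def sample_states(
    params: SystemParams, n: int, seed: int = 0
) -> BinaryRecording:
    """n i.i.d. microstates drawn exactly from the Boltzmann distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    tbl = state_table(params)
    rng = np.random.default_rng(seed)
    idx = rng.choice(tbl.n_states, size=n, p=tbl.probabilities)
    bits = state_matrix(params.n_regions)[idx].astype(np.int8)
    return BinaryRecording(bits, region_labels=params.region_labels)


def random_system(
    n_regions: int,
    seed: int = 0,
    h_scale: float = 0.5,
    j_scale: float = 0.5,
) -> SystemParams:
    """Unstructured random system (for oracle and property tests)."""
    rng = np.random.default_rng(seed)
    h = rng.uniform(-h_scale, h_scale, size=n_regions)
    j = np.zeros((n_regions, n_regions))
    iu = np.triu_indices(n_regions, k=1)
    j[iu] = rng.uniform(-j_scale, j_scale, size=iu[0].size)
    j.T[iu] = j[iu]
    return SystemParams(h=h, j=j)
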