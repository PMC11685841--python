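"""Synthetic ground-truth generators for every pipeline input.

The central object is an epistatic melting-temperature landscape over n
candidate single mutations:

    Tm(v) = Tm_WT + sum_i a_i + sum_(i,j) w_ij + sum_(i,j,k) w_ijk + sign-site bonus

with sparse pairwise/third-order interaction terms.  The default
"creatinase-like" specification emulates the published study's dataset
statistics: 18 candidate sites with single effects roughly in [-2, +2] degC,
exactly 4 deleterious singles and 4 singles above +1 degC, one sign-epistatic
site (deleterious alone, beneficial once at least 3 partner mutations are
present) and one synergistic pair (+1.5 degC beyond additivity), replicate
noise SD 0.3 degC.  Relative activity declines linearly with mutation count.

Every generator is a pure function of (spec, seed): regeneration is
bit-identical, and exact truth (including the global optimum) is available
for any variant, so recovery tests never rely on the code path they check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import Ensemble
from .predictor import VariantRecord
from .variants import AA_ALPHABET, CandidateSet, Mutation, Variant, WILD_TYPE


@dataclass(frozen=True)
class SignEpistasisSpec:
    """A site that is deleterious alone but beneficial with enough partners."""

    site: int                      # candidate index, 0-based
    partners: tuple[int, ...]      # candidate indices
    bonus: float                   # degC, added when >= min_partners present
    min_partners: int = 3


@dataclass(frozen=True)
class LandscapeSpec:
    """Full specification of a synthetic Tm landscape (degC throughout)."""

    n_sites: int
    wt_tm: float
    additive: tuple[float, ...]
    pairwise: tuple[tuple[int, int, float], ...] = ()
    third_order: tuple[tuple[int, int, int, float], ...] = ()
    sign_site: SignEpistasisSpec | None = None
    synergy_pair: tuple[int, int] | None = None   # indices of the planted pair
    noise_sd: float = 0.3
    activity_slope: float = 2.5    # % activity lost per mutation
    activity_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("need at least 2 sites")
        if len(self.additive) != self.n_sites:
            raise ValueError("one additive coefficient per site")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        seen = set()
        for i, j, _ in self.pairwise:
            key = tuple(sorted((i, j)))
            if key in seen:
                raise ValueError(f"pairwise interaction {key} specified twice")
            seen.add(key)
            if not (0 <= i < self.n_sites and 0 <= j < self.n_sites) or i == j:
                raise ValueError(f"invalid pairwise sites {(i, j)}")
        if self.sign_site is not None:
            s = self.sign_site
            if not 0 <= s.site < self.n_sites:
                raise ValueError("sign-epistatic site out of range")
            if any(not 0 <= p < self.n_sites or p == s.site for p in s.partners):
                raise ValueError("sign-site partners out of range")


def synthetic_wild_type(n_sites: int, spacing: int = 3) -> tuple[str, CandidateSet]:
    """A desk-scale parent sequence plus n candidate mutations.

    Each candidate site gets a distinct wild-type residue (n <= 18 <= 20
    letters) so that composition-based surrogate encoders can tell the
    mutations apart — mirroring the real panel, where all candidate singles
    have distinct identities.
    """
    if n_sites > 18:
        raise ValueError("at most 18 candidate sites (need distinct residues)")
    length = spacing * n_sites + spacing
    filler = "G"
    seq = [filler] * length
    letters = [aa for aa in AA_ALPHABET if aa != filler]
    candidates = []
    for i in range(n_sites):
        pos = spacing * (i + 1)            # 1-based positions spacing, 2*spacing, ...
        wt_aa = letters[i]
        mut_aa = letters[(i + n_sites) % len(letters)]
        if mut_aa == wt_aa:
            mut_aa = letters[(i + n_sites + 1) % len(letters)]
        seq[pos - 1] = wt_aa
        candidates.append(Mutation(pos, wt_aa, mut_aa))
    wild_type = "".join(seq)
    return wild_type, CandidateSet(wild_type, tuple(candidates))


class SyntheticLandscape:
    """Exact Tm/activity truth for every variant of a candidate space."""

    def __init__(self, spec: LandscapeSpec):
        self.spec = spec
        self.wild_type, self.candidates = synthetic_wild_type(spec.n_sites)
        self._index = {m: i for i, m in enumerate(self.candidates.candidates)}
        self._tms_cache: np.ndarray | None = None

    # -- truth ---------------------------------------------------------------

    def _mask(self, v: Variant) -> np.ndarray:
        mask = np.zeros(self.spec.n_sites, dtype=bool)
        for m in v.mutations:
            try:
                mask[self._index[m]] = True
            except KeyError:
                raise ValueError(f"mutation {m} is not a candidate of this landscape")
        return mask

    def tm(self, v: Variant) -> float:
        """Exact melting temperature of a variant (degC)."""
        return float(self._tm_from_mask(self._mask(v)))

    def _tm_from_mask(self, mask: np.ndarray) -> float:
        s = self.spec
        tm = s.wt_tm + float(np.dot(mask, s.additive))
        for i, j, w in s.pairwise:
            if mask[i] and mask[j]:
                tm += w
        for i, j, k, w in s.third_order:
            if mask[i] and mask[j] and mask[k]:
                tm += w
        if s.sign_site is not None:
            ss = s.sign_site
            if mask[ss.site] and sum(mask[p] for p in ss.partners) >= ss.min_partners:
                tm += ss.bonus
        return tm

    def activity(self, v: Variant) -> float:
        """Exact relative activity (% of wild type)."""
        return max(0.0, 100.0 - self.spec.activity_slope * v.order)

    def variant_from_indices(self, indices: Sequence[int]) -> Variant:
        return Variant([self.candidates.candidates[i] for i in indices])

    # -- exhaustive truth over the whole 2^n space ----------------------------

    def exhaustive_tms(self) -> np.ndarray:
        """Tm of every variant, indexed by candidate bitmask (vectorized)."""
        if self._tms_cache is not None:
            return self._tms_cache
        s = self.spec
        n = s.n_sites
        masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1   # (2^n, n)
        masks = masks.astype(bool)
        tms = s.wt_tm + masks @ np.asarray(s.additive)
        for i, j, w in s.pairwise:
            tms += w * (masks[:, i] & masks[:, j])
        for i, j, k, w in s.third_order:
            tms += w * (masks[:, i] & masks[:, j] & masks[:, k])
        if s.sign_site is not None:
            ss = s.sign_site
            enough = masks[:, list(ss.partners)].sum(axis=1) >= ss.min_partners
            tms += ss.bonus * (masks[:, ss.site] & enough)
        self._tms_cache = tms
        return tms

    def optimum(self) -> tuple[Variant, float]:
        """The global Tm optimum, found by exhaustive enumeration."""
        tms = self.exhaustive_tms()
        best = int(np.argmax(tms))
        indices = [i for i in range(self.spec.n_sites) if best >> i & 1]
        return self.variant_from_indices(indices), float(tms[best])

    # -- noisy measurement ----------------------------------------------------

    def sample_records(self, variants: Sequence[Variant], seed: int,
                       round_index: int = 0,
                       noise_sd: float | None = None) -> list[VariantRecord]:
        """Measure variants: truth plus seeded Gaussian noise on both labels."""
        rng = np.random.default_rng(seed)
        sd = self.spec.noise_sd if noise_sd is None else noise_sd
        out = []
        for v in variants:
            out.append(VariantRecord(
                variant=v,
                tm=self.tm(v) + (rng.normal(0.0, sd) if sd > 0 else 0.0),
                relative_activity=max(
                    0.0,
                    self.activity(v)
                    + (rng.normal(0.0, self.spec.activity_noise_sd)
                       if self.spec.activity_noise_sd > 0 else 0.0),
                ),
                round=round_index,
            ))
        return out


def generate_landscape(spec: LandscapeSpec) -> SyntheticLandscape:
    return SyntheticLandscape(spec)


def creatinase_like_spec(n_sites: int = 18, noise_sd: float = 0.3,
                         seed: int = 0) -> LandscapeSpec:
    """The default study-like landscape.

    4 deleterious singles (the first is the sign-epistatic site, -0.9 degC
    alone, +2.0 degC once >= 3 of its 5 partner mutations are present), 4
    singles above +1 degC, the rest mildly beneficial, and one synergistic
    pair (+1.5 degC beyond additivity) between a strong and a moderate site.
    Works for n_sites >= 10; the interaction structure keeps the same shape
    as n scales down.
    """
    if n_sites < 10:
        raise ValueError("creatinase-like spec needs at least 10 sites")
    negatives = [-0.9, -0.6, -0.4, -0.3]
    strong = [1.6, 1.4, 1.2, 1.1]
    n_mod = n_sites - 8
    moderates = list(np.round(np.linspace(0.2, 0.9, n_mod), 3))
    additive = tuple(negatives + strong + moderates)
    sign = SignEpistasisSpec(site=0, partners=(4, 5, 6, 7, 8), bonus=2.0,
                             min_partners=3)
    synergy = (4, 8)
    return LandscapeSpec(
        n_sites=n_sites,
        wt_tm=59.53,
        additive=additive,
        pairwise=((synergy[0], synergy[1], 1.5),),
        sign_site=sign,
        synergy_pair=synergy,
        noise_sd=noise_sd,
        seed=seed,
    )


def additive_control_spec(n_sites: int = 6, noise_sd: float = 0.1,
                          seed: int = 0) -> LandscapeSpec:
    """A purely additive landscape for false-positive controls.

    Coefficients have magnitude in [0.5, 2.0] with random sign: mutations
    entering a combination campaign are pre-screened for a measurable single
    effect, so near-zero coefficients are not representative.
    """
    rng = np.random.default_rng(seed)
    mags = rng.uniform(0.5, 2.0, size=n_sites)
    signs = rng.choice([-1.0, 1.0], size=n_sites)
    return LandscapeSpec(
        n_sites=n_sites,
        wt_tm=59.53,
        additive=tuple(np.round(mags * signs, 4)),
        noise_sd=noise_sd,
        seed=seed,
    )


def default_initial_counts(n_sites: int) -> tuple[int, int, int, int]:
    """Study-like per-order counts (18, 22, 21, 12), capped by the space size."""
    from math import comb

    base = (18, 22, 21, 12)
    return tuple(min(c, comb(n_sites, k)) for k, c in enumerate(base, start=1))


def sample_initial_dataset(
    landscape: SyntheticLandscape,
    counts: Sequence[int] = (18, 22, 21, 12),
    include_wt: bool = True,
    seed: int = 0,
) -> list[VariantRecord]:
    """Draw the study-like initial dataset: singles, doubles, triples, quads.

    ``counts[k-1]`` variants of order k are sampled without replacement
    (default 18/22/21/12 = 73 records, plus the wild-type record when
    ``include_wt`` — 74 total).  Labels are truth plus seeded noise.
    """
    rng = np.random.default_rng(seed)
    n = landscape.spec.n_sites
    from math import comb

    variants: list[Variant] = []
    for k, count in enumerate(counts, start=1):
        available = comb(n, k)
        if count > available:
            raise ValueError(f"requested {count} variants of order {k}, "
                             f"only {available} exist")
        chosen: set[tuple[int, ...]] = set()
        while len(chosen) < count:
            pick = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
            chosen.add(pick)
        variants.extend(landscape.variant_from_indices(p) for p in sorted(chosen))
    if include_wt:
        variants.insert(0, WILD_TYPE)
    return landscape.sample_records(variants, seed=seed + 1, round_index=0)


# ---------------------------------------------------------------------------
# raw assay curves
# ---------------------------------------------------------------------------

MM_SUBSTRATE_MM = (0.5, 2, 5, 8, 10, 14, 18, 30, 50, 80, 120)

_CURVE_DEFAULTS = {
    # Table-scale wild-type parameters
    "dsf": {"tm": 59.53, "slope": 1.2, "y_lo": 0.0, "y_hi": 1.0},
    "cd": {"tm": 60.18, "slope": 1.5, "y_lo": -20.0, "y_hi": -2.0},
    "t50": {"tm": 52.86, "slope": 1.5, "y_lo": 100.0, "y_hi": 0.0},
    "dsc": {"tm": 60.29, "dh": 614.5, "b0": 0.0, "b1": 0.0},
    "decay": {"t_half": 1.60, "a0": 100.0, "n_points": 12},
    "mm": {"km": 10.46, "vmax": 1.0, "enzyme_conc": None},
}


def generate_assay_curves(modality: str, params: dict | None = None,
                          noise: float = 0.02, seed: int = 0,
                          sample: str = "sample") -> tuple[pd.DataFrame, dict]:
    """Generate one raw assay curve from the exact model its fitter assumes.

    Returns (long-format table ``sample,series_type,x,y``, truth dict).
    Modalities: ``dsf`` / ``cd`` / ``t50`` (Boltzmann sigmoids), ``dsc``
    (two-state thermogram), ``decay`` (first-order inactivation), ``mm``
    (Michaelis-Menten).

    ``noise`` is the Gaussian SD.  For the optical/calorimetric signals
    (dsf, cd, t50, dsc) it is additive, as a fraction of the curve amplitude
    (detector noise).  For activity-based measurements (decay, mm) it is
    multiplicative — a constant coefficient of variation, the standard error
    structure of coupled enzymatic assays, which also keeps rates positive.
    """
    if modality not in _CURVE_DEFAULTS:
        raise ValueError(f"unknown modality {modality!r}")
    p = {**_CURVE_DEFAULTS[modality], **(params or {})}
    rng = np.random.default_rng(seed)

    if modality in ("dsf", "cd", "t50"):
        from .assays import _boltzmann
        if modality == "dsf":
            x = np.arange(25.0, 95.0 + 1e-9, 0.5)
        elif modality == "cd":
            x = np.arange(25.0, 80.0 + 1e-9, 2.0)
        else:
            x = np.arange(25.0, 70.0 + 1e-9, 1.5)
        y = _boltzmann(x, p["y_lo"], p["y_hi"], p["tm"], p["slope"])
        amplitude = abs(p["y_hi"] - p["y_lo"])
    elif modality == "dsc":
        from .assays import _dsc_two_state
        x = np.arange(p["tm"] - 20.0, p["tm"] + 20.0 + 1e-9, 0.25)
        y = _dsc_two_state(x, p["tm"], p["dh"], p["b0"], p["b1"])
        amplitude = float(y.max() - y.min())
    elif modality == "decay":
        k = -np.log(2.0) / p["t_half"]
        x = np.linspace(0.0, 4.0 * p["t_half"], p["n_points"])
        y = p["a0"] * np.exp(k * x)
        amplitude = p["a0"]
        p["k"] = k
    else:  # mm
        x = np.asarray(p.get("substrate_mM", MM_SUBSTRATE_MM), dtype=float)
        y = p["vmax"] * x / (p["km"] + x)
        amplitude = p["vmax"]

    if noise > 0:
        if modality in ("decay", "mm"):
            y = y * (1.0 + rng.normal(0.0, noise, size=y.shape))
        else:
            y = y + rng.normal(0.0, noise * amplitude, size=y.shape)

    df = pd.DataFrame({
        "sample": sample,
        "series_type": modality,
        "x": x,
        "y": y,
    })
    return df, p


# ---------------------------------------------------------------------------
# correlated coordinate ensembles
# ---------------------------------------------------------------------------


def generate_correlated_ensemble(
    n_atoms: int,
    covariance: np.ndarray,
    frames: int = 500,
    seed: int = 0,
    mean_structure: np.ndarray | None = None,
) -> tuple[Ensemble, np.ndarray]:
    """Ensemble of Gaussian displacements with a prescribed atom covariance.

    ``covariance`` is the N x N per-axis displacement covariance, applied
    independently to x, y and z, so the analytic displacement-vector
    correlation equals ``cov_ij / sqrt(cov_ii cov_jj)``; that analytic DCCM
    is returned alongside the ensemble.
    """
    cov = np.asarray(covariance, dtype=float)
    if cov.shape != (n_atoms, n_atoms):
        raise ValueError(f"covariance must be ({n_atoms}, {n_atoms})")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    w, V = np.linalg.eigh(cov)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("covariance must be positive semi-definite")
    L = V * np.sqrt(np.clip(w, 0.0, None))

    if mean_structure is None:
        mean_structure = np.zeros((n_atoms, 3))
        mean_structure[:, 0] = 3.8 * np.arange(n_atoms)   # CA-like chain spacing
        mean_structure[:, 1] = 1.5 * np.sin(np.arange(n_atoms))
        mean_structure[:, 2] = 1.5 * np.cos(np.arange(n_atoms))

    rng = np.random.default_rng(seed)
    coords = np.empty((frames, n_atoms, 3))
    for axis in range(3):
        Z = rng.standard_normal((frames, n_atoms))
        coords[:, :, axis] = mean_structure[:, axis] + Z @ L.T

    var = np.diag(cov).copy()
    safe = var.copy()
    safe[safe <= 0] = 1.0
    analytic = cov / np.sqrt(np.outer(safe, safe))
    zero = var <= 0
    if zero.any():
        analytic[zero, :] = np.nan
        analytic[:, zero] = np.nan
    return Ensemble(coords, superposed=True), analytic
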