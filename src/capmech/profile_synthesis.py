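"""Synthetic steady footprint profiles of capsules in tube flow.

This module is the forward model of the package: it produces the steady
footprint (silhouette) outline of an initially spherical capsule flowing
along a capillary tube, as a smooth, deterministic function of the membrane
law family and the two capillary numbers, plus camera-style rasterisations of
those outlines. It replaces a full fluid–structure simulation with a
phenomenological shape family that reproduces the features an inverse method
relies on:

* the undeformed limit (Ca -> 0) is a circle of radius ``(1 + alpha) beta``
  in tube-radius units;
* the profile elongates along the flow axis as ``Ca^Gs`` grows and develops
  a flattened-to-concave rear (bullet -> parachute) as ``Ca^Ks`` grows;
* the enclosed volume of the solid of revolution is conserved at the inflated
  sphere volume ``(4/3) pi ((1 + alpha) beta)^3``;
* Skalak and Hooke membranes with matched ``(Gs, Ks)`` — i.e. matched
  ``(Ca^Gs, Ca^Ks)`` — produce identical footprints, mirroring the observed
  near-degeneracy of the two laws at moderate deformation, while a small
  extra shape mode keeps the neo-Hookean family identifiable.

The parametric form (a polar mode expansion of the generatrix) and its gain
constants are fixed, documented constants of the package; they are a shape
phenomenology, not a fit to any published figure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.integrate import simpson

from .membrane_laws import LAW_ORDER, LawKind, equivalent_parameters

__all__ = [
    "CapsuleProfile",
    "CapsuleImage",
    "LabelledSample",
    "Dataset",
    "steady_profile",
    "rasterize",
    "generate_dataset",
    "BETA_DEFAULT",
    "ALPHA_DEFAULT",
    "CA_KS_RANGE",
    "CA_GS_RANGE",
    "VALIDITY_BOX",
]

# Study conditions: confinement and pre-inflation of the reference experiments,
# and the capillary-number box covered by the training data.
BETA_DEFAULT = 0.77
ALPHA_DEFAULT = 0.03
CA_KS_RANGE: Tuple[float, float] = (0.02, 0.055)
CA_GS_RANGE: Tuple[float, float] = (0.03, 0.21)
# Admissible generator inputs; extends to zero so the undeformed limit exists.
VALIDITY_BOX: Tuple[Tuple[float, float], Tuple[float, float]] = (
    (0.0, CA_KS_RANGE[1]),
    (0.0, CA_GS_RANGE[1]),
)

# Reference scales turning capillary numbers into O(1) deformation drivers.
_CA_KS_REF = CA_KS_RANGE[1]
_CA_GS_REF = CA_GS_RANGE[1]

# Shape-mode gains (fractions of the inflated radius at the top of the Ca box).
_ELONGATION_GAIN = 0.18  # cos(2 theta): axial stretch, driven by Ca^Gs
_ASYMMETRY_GAIN = 0.06  # cos(theta): front/rear asymmetry, driven by Ca^Ks
_DIMPLE_GAIN = 0.22  # rear bump: parachute concavity, driven by Ca^Ks
_NH_MODE_GAIN = 0.05  # cos(3 theta): neo-Hookean-only perturbation

_N_DENSE = 4096  # dense generatrix sampling before arc-length resampling


@dataclass
class CapsuleProfile:
    """Closed, counter-clockwise, centroid-centred footprint polyline.

    Coordinates are nondimensionalised by the tube radius R; the flow axis is
    +x and the tube walls sit at y = +-1.
    """

    nodes: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        if nodes.ndim != 2 or nodes.shape[1] != 2 or nodes.shape[0] < 3:
            raise ValueError("nodes must be an (N >= 3, 2) array")
        self.nodes = nodes

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def signed_area(self) -> float:
        x, y = self.nodes[:, 0], self.nodes[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def centroid(self) -> np.ndarray:
        """Area centroid of the enclosed polygon."""
        x, y = self.nodes[:, 0], self.nodes[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = 0.5 * np.sum(cross)
        if abs(a) < 1e-300:
            return self.nodes.mean(axis=0)
        cx = np.sum((x + xn) * cross) / (6.0 * a)
        cy = np.sum((y + yn) * cross) / (6.0 * a)
        return np.array([cx, cy])

    @property
    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.roll(self.nodes, -1, axis=0) - self.nodes, axis=1)

    @property
    def spacing_cv(self) -> float:
        """Coefficient of variation of consecutive arc spacings."""
        e = self.edge_lengths
        return float(np.std(e) / np.mean(e))

    @property
    def tip_to_tail(self) -> float:
        """Axial extent (length along the flow direction)."""
        return float(self.nodes[:, 0].max() - self.nodes[:, 0].min())

    def revolved_volume(self) -> float:
        """Volume of the solid of revolution of the polyline about the x axis.

        Uses V = (pi/2) |oint y |y| dx|, which reduces to pi * int y_up^2 dx
        for a curve symmetric about the axis and degrades gracefully for
        slightly noisy, nearly symmetric curves.
        """
        x, y = self.nodes[:, 0], self.nodes[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        f, fn = y * np.abs(y), yn * np.abs(yn)
        return 0.5 * np.pi * abs(float(np.sum(0.5 * (f + fn) * (xn - x))))

    def validate(self, inside_tube: bool = True) -> None:
        """Raise if the profile violates its structural invariants."""
        if self.signed_area <= 0:
            raise ValueError("profile must be counter-clockwise (signed area > 0)")
        if np.linalg.norm(self.centroid) > 1e-9:
            raise ValueError("profile must be centred on its polygon centroid")
        if self.spacing_cv > 0.01:
            raise ValueError("node arc spacing coefficient of variation exceeds 1%")
        if inside_tube and np.any(np.abs(self.nodes[:, 1]) >= 1.0):
            raise ValueError("profile exceeds the tube wall |y| < 1")

    def recentre(self) -> "CapsuleProfile":
        return CapsuleProfile(self.nodes - self.centroid)

    # -- plain-text IO -----------------------------------------------------
    def to_csv(self, path: Union[str, Path]) -> None:
        n = self.n_nodes
        arr = np.column_stack([np.arange(n), self.nodes])
        header = "node,x,y"
        np.savetxt(path, arr, delimiter=",", header=header, comments="",
                   fmt=["%d", "%.12g", "%.12g"])

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "CapsuleProfile":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(arr[:, 1:3])


@dataclass
class CapsuleImage:
    """Grayscale raster of a capsule footprint.

    ``px_per_diameter`` is the camera resolution expressed as pixels across
    the *undeformed* capsule diameter — the field's resolution descriptor.
    """

    pixels: np.ndarray
    px_per_diameter: float
    background_level: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D grid")
        if not self.px_per_diameter > 0:
            raise ValueError("px_per_diameter must be positive")


@dataclass
class LabelledSample:
    """One training/testing sample: feature vector plus ground-truth labels."""

    vector: np.ndarray
    law_kind: LawKind
    ca_ks: float
    ca_gs: float

    def profile(self) -> CapsuleProfile:
        return CapsuleProfile(np.asarray(self.vector, dtype=float).reshape(-1, 2))


@dataclass
class Dataset:
    """A labelled collection of synthetic samples plus its generation manifest."""

    samples: List[LabelledSample]
    manifest: Dict

    def __len__(self) -> int:
        return len(self.samples)

    def matrices(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, class_index, y) arrays: vectors, law index in LAW_ORDER, (CaKs, CaGs)."""
        X = np.stack([s.vector for s in self.samples])
        z = np.array([LAW_ORDER.index(s.law_kind) for s in self.samples])
        y = np.array([[s.ca_ks, s.ca_gs] for s in self.samples])
        return X, z, y

    # -- directory IO ------------------------------------------------------
    def save(self, directory: Union[str, Path]) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        rows = []
        for i, s in enumerate(self.samples):
            s.profile().to_csv(d / f"sample_{i:05d}.csv")
            rows.append(f"{i},{s.law_kind.value},{s.ca_ks:.12g},{s.ca_gs:.12g}")
        (d / "labels.csv").write_text("sample,law,ca_ks,ca_gs\n" + "\n".join(rows) + "\n")

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "Dataset":
        from .boundary_extraction import to_feature_vector

        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        samples = []
        for line in (d / "labels.csv").read_text().strip().splitlines()[1:]:
            idx, law, ca_ks, ca_gs = line.split(",")
            profile = CapsuleProfile.from_csv(d / f"sample_{int(idx):05d}.csv")
            samples.append(
                LabelledSample(
                    vector=to_feature_vector(profile).values,
                    law_kind=LawKind.coerce(law),
                    ca_ks=float(ca_ks),
                    ca_gs=float(ca_gs),
                )
            )
        return cls(samples=samples, manifest=manifest)


def _radial_modes(
    kind: LawKind, ca_ks: float, ca_gs: float, theta: np.ndarray
) -> np.ndarray:
    """Dimensionless radial multiplier r(theta)/r0 of the shape family."""
    d1 = ca_ks / _CA_KS_REF
    d2 = ca_gs / _CA_GS_REF
    elong = _ELONGATION_GAIN * d2
    asym = _ASYMMETRY_GAIN * d1
    dimple = _DIMPLE_GAIN * d1**2
    bump = ((1.0 - np.cos(theta)) / 2.0) ** 4  # smooth, peaked at the rear
    r = 1.0 + elong * np.cos(2.0 * theta) + asym * np.cos(theta) - dimple * bump
    if kind is LawKind.NEO_HOOKEAN:
        r = r + _NH_MODE_GAIN * 0.5 * (d1 + d2) * np.cos(3.0 * theta)
    return r


def steady_profile(
    kind: Union[LawKind, str],
    ca_ks: float,
    ca_gs: float,
    beta: float = BETA_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    n_nodes: int = 60,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    validity_box: Tuple[Tuple[float, float], Tuple[float, float]] = VALIDITY_BOX,
) -> CapsuleProfile:
    """Steady footprint profile of a capsule in tube flow.

    Returns a closed, counter-clockwise polyline of ``n_nodes`` points with
    equal arc spacing, centred on its polygon centroid, in tube-radius units.
    The solid of revolution of the underlying generatrix encloses the inflated
    sphere volume (4/3) pi ((1 + alpha) beta)^3. ``noise_sd`` applies a
    zero-mean Gaussian radial perturbation to the nodes (in units of the
    inflated radius) before a final volume renormalisation; the result is
    deterministic given ``seed``.
    """
    kind = LawKind.coerce(kind)
    (ks_lo, ks_hi), (gs_lo, gs_hi) = validity_box
    if not (ks_lo <= ca_ks <= ks_hi and gs_lo <= ca_gs <= gs_hi):
        raise ValueError(
            f"(Ca^Ks, Ca^Gs) = ({ca_ks}, {ca_gs}) outside validity box {validity_box}"
        )
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie in (0, 1)")
    if beta * (1.0 + alpha) >= 1.0:
        raise ValueError("inflated capsule does not fit in the tube: beta (1+alpha) >= 1")
    if n_nodes < 10:
        raise ValueError("n_nodes must be at least 10")

    r0 = beta * (1.0 + alpha)
    theta = np.linspace(0.0, 2.0 * np.pi, _N_DENSE + 1)
    r = r0 * _radial_modes(kind, ca_ks, ca_gs, theta)

    # Volume normalisation of the axisymmetric generatrix:
    # V = (2 pi / 3) int_0^pi r^3 sin(theta) d theta  ->  scale so V = V_sphere.
    half = theta <= np.pi
    v_raw = (2.0 * np.pi / 3.0) * simpson(r[half] ** 3 * np.sin(theta[half]),
                                          x=theta[half])
    v_target = (4.0 / 3.0) * np.pi * r0**3
    r = r * (v_target / v_raw) ** (1.0 / 3.0)

    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    # Equal arc-length resampling of the dense closed curve.
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n_nodes) * (s[-1] / n_nodes)
    nodes = np.column_stack(
        [np.interp(targets, s, pts[:, 0]), np.interp(targets, s, pts[:, 1])]
    )

    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        radii = np.linalg.norm(nodes, axis=1)
        scale = 1.0 + noise_sd * r0 * rng.standard_normal(n_nodes) / np.maximum(radii, 1e-12)
        nodes = nodes * scale[:, None]
        prof = CapsuleProfile(nodes)
        v_now = prof.revolved_volume()
        if v_now > 0:
            nodes = nodes * (v_target / v_now) ** (1.0 / 3.0)

    profile = CapsuleProfile(nodes).recentre()
    if np.any(np.abs(profile.nodes[:, 1]) >= 1.0):
        raise ValueError("generated profile exceeds the tube wall")
    return profile


def rasterize(
    profile: CapsuleProfile,
    px_per_diameter: float,
    background_level: float = 200.0,
    pixel_noise_sd: float = 0.0,
    seed: Optional[int] = None,
    foreground_level: float = 60.0,
    capsule_diameter_tr: float = 2.0 * BETA_DEFAULT * (1.0 + ALPHA_DEFAULT),
    margin_px: int = 4,
) -> CapsuleImage:
    """Camera-style raster of a footprint profile.

    The image is a square covering the tube bore (y in [-1, 1]) plus a small
    margin; pixels whose centres fall inside the polygon take
    ``foreground_level``, all others ``background_level`` (binary construction,
    no anti-aliasing). ``capsule_diameter_tr`` is the undeformed capsule
    diameter in tube-radius units, which converts ``px_per_diameter`` into a
    pixel pitch. Optional additive Gaussian pixel noise is seeded.
    """
    if px_per_diameter < 16:
        raise ValueError("px_per_diameter must be at least 16")
    scale = px_per_diameter / capsule_diameter_tr  # px per tube radius
    side = int(round(2.0 * scale)) + 2 * margin_px
    c = (side - 1) / 2.0

    ext = np.max(np.abs(profile.nodes)) * scale
    if ext > c:
        raise ValueError("profile exceeds the image bounds")

    jj, ii = np.meshgrid(np.arange(side), np.arange(side))  # ii rows, jj cols
    # Pixel-centre coordinates in tube-radius units, image y flipped to math.
    xs = (jj - c) / scale
    ys = (c - ii) / scale
    inside = MplPath(profile.nodes).contains_points(
        np.column_stack([xs.ravel(), ys.ravel()])
    ).reshape(side, side)

    pixels = np.full((side, side), float(background_level))
    pixels[inside] = float(foreground_level)
    if pixel_noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        pixels = pixels + pixel_noise_sd * rng.standard_normal(pixels.shape)
    return CapsuleImage(pixels=pixels, px_per_diameter=px_per_diameter,
                        background_level=float(background_level))


def background_image(image: CapsuleImage) -> CapsuleImage:
    """The empty-field frame matching ``image`` (uniform background level)."""
    return CapsuleImage(
        pixels=np.full_like(image.pixels, image.background_level),
        px_per_diameter=image.px_per_diameter,
        background_level=image.background_level,
    )


def _draw_ca_pair(
    rng: np.random.Generator,
    kind: LawKind,
    ca_ks_range: Tuple[float, float],
    ca_gs_range: Tuple[float, float],
) -> Tuple[float, float]:
    """Draw (Ca^Ks, Ca^Gs) respecting the law's Ks/Gs consistency constraint."""
    if kind is LawKind.NEO_HOOKEAN:
        # Ks = 3 Gs forces Ca^Gs = 3 Ca^Ks; sample along that line.
        lo = max(ca_ks_range[0], ca_gs_range[0] / 3.0)
        hi = min(ca_ks_range[1], ca_gs_range[1] / 3.0)
        if not lo < hi:
            raise ValueError("NH line Ca^Gs = 3 Ca^Ks does not intersect the ranges")
        ca_ks = rng.uniform(lo, hi)
        return ca_ks, 3.0 * ca_ks
    # SK / Hooke: any ratio Ks/Gs > 1 is admissible (C > 0, 0 < nu_s < 1).
    for _ in range(10_000):
        ca_ks = rng.uniform(*ca_ks_range)
        ca_gs = rng.uniform(*ca_gs_range)
        if ca_gs > ca_ks * (1.0 + 1e-9):
            return ca_ks, ca_gs
    raise RuntimeError("rejection sampling failed to find Ca^Gs > Ca^Ks")


def generate_dataset(
    n: int,
    ca_ks_range: Tuple[float, float] = CA_KS_RANGE,
    ca_gs_range: Tuple[float, float] = CA_GS_RANGE,
    law_mix: Sequence[float] = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0),
    beta: float = BETA_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    n_nodes: int = 60,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Dataset:
    """Generate ``n`` labelled samples with uniform Ca draws per law.

    ``law_mix`` gives the (NH, SK, Hooke) fractions; counts are assigned by
    largest remainder so the total is exactly ``n``. Each law's Ks/Gs
    consistency is enforced: NH samples sit on Ca^Gs = 3 Ca^Ks, SK/Hooke
    draws are rejected until Ca^Gs > Ca^Ks (positive C / nu_s). The dataset
    is bit-for-bit reproducible from its manifest.
    """
    from .boundary_extraction import to_feature_vector

    mix = np.asarray(law_mix, dtype=float)
    if mix.shape != (3,) or abs(mix.sum() - 1.0) > 1e-9 or np.any(mix < 0):
        raise ValueError("law_mix must be three non-negative fractions summing to 1")
    k_lo, k_hi = ca_ks_range
    g_lo, g_hi = ca_gs_range
    if not (VALIDITY_BOX[0][0] <= k_lo <= k_hi <= VALIDITY_BOX[0][1]
            and VALIDITY_BOX[1][0] <= g_lo <= g_hi <= VALIDITY_BOX[1][1]):
        raise ValueError("requested Ca ranges fall outside the generator validity box")

    floors = np.floor(mix * n).astype(int)
    remainder = n - floors.sum()
    order = np.argsort(-(mix * n - floors))
    counts = floors.copy()
    for i in range(remainder):
        counts[order[i % 3]] += 1

    rng = np.random.default_rng(seed)
    samples: List[LabelledSample] = []
    for kind, count in zip(LAW_ORDER, counts):
        for _ in range(count):
            ca_ks, ca_gs = _draw_ca_pair(rng, kind, ca_ks_range, ca_gs_range)
            node_seed = int(rng.integers(0, 2**31 - 1))
            prof = steady_profile(
                kind, ca_ks, ca_gs, beta=beta, alpha=alpha, n_nodes=n_nodes,
                noise_sd=noise_sd, seed=node_seed,
            )
            samples.append(
                LabelledSample(
                    vector=to_feature_vector(prof).values,
                    law_kind=kind,
                    ca_ks=ca_ks,
                    ca_gs=ca_gs,
                )
            )

    manifest = {
        "n": n,
        "seed": seed,
        "ca_ks_range": list(ca_ks_range),
        "ca_gs_range": list(ca_gs_range),
        "law_mix": mix.tolist(),
        "beta": beta,
        "alpha": alpha,
        "n_nodes": n_nodes,
        "noise_sd": noise_sd,
        "law_counts": {k.value: int(c) for k, c in zip(LAW_ORDER, counts)},
    }
    return Dataset(samples=samples, manifest=manifest)


def law_parameters_for_sample(sample: LabelledSample):
    """Law-specific parameters implied by a sample's capillary numbers.

    The Ks/Gs ratio equals Ca^Gs / Ca^Ks; for SK and Hooke the law parameter
    follows from the equivalence relations (Gs is left at unity, since only
    ratios are observable without a dimensional flow condition).
    """
    from .membrane_laws import LawParameters

    ratio = sample.ca_gs / sample.ca_ks
    if sample.law_kind is LawKind.NEO_HOOKEAN:
        return LawParameters(kind=LawKind.NEO_HOOKEAN, Gs=1.0)
    c, nu = equivalent_parameters(ratio)
    if sample.law_kind is LawKind.SKALAK:
        return LawParameters(kind=LawKind.SKALAK, Gs=1.0, C=c)
    return LawParameters(kind=LawKind.HOOKE, Gs=1.0, nu_s=nu)
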