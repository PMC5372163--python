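"""Synthetic fixtures with known ground truth.

Tissue phantoms are built from Gaussian-band class signatures scaled by a
per-pixel concentration (Lambert-Beer), distorted by van de Hulst Mie
extinction curves with per-pixel sphere parameters, and degraded with white
noise plus planted defect pixels (blank cracks, saturated folds).  Reference
point sets are produced by pushing random fiducials through a known
similarity transform, and protein tables carry log-normal abundances with
planted multiplicative group effects.  Every generator is a pure function of
its parameters and seed.

These phantoms emulate the *structure* of infrared tissue data — band
shapes, concentration scaling, scattering baselines — not the biology; no
claim of spectral fidelity to real tissue classes is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ParameterError
from .hyperspec_io import (
    LabelMap,
    ProteinAbundanceTable,
    ReferencePointSet,
    SpectralImage,
    WavenumberAxis,
)
from .preprocess import mie_extinction
from .roi_transfer import HelmertTransform

__all__ = [
    "ClassSignature",
    "PhantomSpec",
    "default_signatures",
    "generate_phantom",
    "generate_reference_points",
    "generate_protein_table",
    "load_marker_panel",
]


@dataclass(frozen=True)
class ClassSignature:
    """Gaussian-band spectral signature of one synthetic tissue class.

    Every signature carries an amide I band near 1654 cm^-1 so that quality
    control and the concentration proxy are meaningful.
    """

    name: str
    bands: tuple[tuple[float, float, float], ...]  # (center cm^-1, sigma, amplitude)
    baseline_offset: float = 0.0

    def __post_init__(self) -> None:
        if any(amp < 0 for _, _, amp in self.bands):
            raise ParameterError("band amplitudes must be nonnegative")
        has_amide = any(
            1630 <= center <= 1680 and amp > 0 for center, _, amp in self.bands
        )
        if not has_amide:
            raise ParameterError(
                f"signature '{self.name}' lacks an amide I band near 1654 cm^-1"
            )

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        nu = np.asarray(wavenumbers, dtype=float)
        spectrum = np.full_like(nu, self.baseline_offset)
        for center, sigma, amp in self.bands:
            spectrum = spectrum + amp * np.exp(-0.5 * ((nu - center) / sigma) ** 2)
        return spectrum


def default_signatures() -> dict[str, ClassSignature]:
    """Three spectroscopically plausible classes: two tumour-like signatures
    differing in amide I/II ratio and lipid band, one collagen-rich stroma.
    """
    return {
        "epithelioid": ClassSignature(
            "epithelioid",
            bands=(
                (1654.0, 25.0, 0.60),  # amide I (same amplitude for every
                # class so the band integral is a pure concentration proxy)
                (1545.0, 18.0, 0.36),  # amide II
                (1740.0, 14.0, 0.06),  # ester carbonyl (lipid-like)
                (1080.0, 28.0, 0.10),  # carbohydrate / phosphate
            ),
        ),
        "sarcomatoid": ClassSignature(
            "sarcomatoid",
            bands=(
                (1654.0, 25.0, 0.60),
                (1545.0, 18.0, 0.24),
                (1740.0, 14.0, 0.18),
                (1080.0, 28.0, 0.04),
            ),
        ),
        "stroma": ClassSignature(
            "stroma",
            bands=(
                (1654.0, 25.0, 0.60),
                (1545.0, 18.0, 0.30),
                (1236.0, 24.0, 0.20),  # amide III / collagen-like
                (1032.0, 26.0, 0.20),
            ),
        ),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Layout and degradation parameters of a hyperspectral phantom.

    Blob classes are stamped as random disks over an optional background
    tissue class; the rest is bare substrate (zero absorbance).  Defect
    pixels emulate cracks (blank) and folds (saturated).
    """

    shape: tuple[int, int] = (64, 64)
    blob_classes: dict[str, tuple[int, tuple[float, float]]] = field(
        default_factory=lambda: {"epithelioid": (3, (6.0, 12.0)), "sarcomatoid": (3, (6.0, 12.0))}
    )
    background_class: str | None = "stroma"
    concentration_range: tuple[float, float] = (0.8, 1.2)
    mie_fraction: float = 0.1
    mie_radius_range_um: tuple[float, float] = (2.0, 8.0)
    mie_n_range: tuple[float, float] = (1.1, 1.5)
    noise_sigma: float = 0.005
    n_blank: int = 10
    n_saturated: int = 5
    saturation_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentration_range[0] <= 0:
            raise ParameterError("concentrations must be positive")
        if self.mie_fraction < 0 or self.noise_sigma < 0:
            raise ParameterError("mie_fraction and noise_sigma must be nonnegative")


def generate_phantom(
    spec: PhantomSpec,
    signatures: dict[str, ClassSignature] | None = None,
    axis: WavenumberAxis | None = None,
    pixel_size: tuple[float, float] = (5.5, 5.5),
    stage_origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[SpectralImage, LabelMap, np.ndarray, dict]:
    """Generate (image, truth label map, concentration map, truth metadata).

    Per tissue pixel the spectrum is ``concentration x signature +
    mie_fraction x Q(nu; r, n) + N(0, noise_sigma)`` with sphere radius and
    refractive index drawn per pixel.  Blank defects are exactly zero,
    saturated defects scaled far above the quality-control band; both are
    labelled 0 in the truth map and listed in the metadata.  Bit-identical
    for identical spec + seed.
    """
    signatures = signatures or default_signatures()
    axis = axis or WavenumberAxis.acquisition_default()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    nu = axis.values

    class_names = list(spec.blob_classes.keys())
    if spec.background_class is not None:
        class_names = [spec.background_class] + [
            c for c in class_names if c != spec.background_class
        ]
    for name in class_names:
        if name not in signatures:
            raise ParameterError(f"no signature for class '{name}'")
    name_to_label = {name: i + 1 for i, name in enumerate(class_names)}

    labels = np.zeros((rows, cols), dtype=np.int32)
    if spec.background_class is not None:
        labels[:] = name_to_label[spec.background_class]
    for name, (count, (r_min, r_max)) in spec.blob_classes.items():
        for _ in range(count):
            cr, cc = rng.uniform(0, rows), rng.uniform(0, cols)
            radius = rng.uniform(r_min, r_max)
            rr, cc_grid = np.ogrid[:rows, :cols]
            disk = (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= radius**2
            labels[disk] = name_to_label[name]

    tissue = labels > 0
    concentration = np.zeros((rows, cols))
    concentration[tissue] = rng.uniform(*spec.concentration_range, size=int(tissue.sum()))

    cube = np.zeros((rows, cols, nu.size))
    sig_vectors = {name: signatures[name].evaluate(nu) for name in class_names}
    for name in class_names:
        sel = labels == name_to_label[name]
        cube[sel] = concentration[sel, None] * sig_vectors[name][None, :]

    if spec.mie_fraction > 0:
        radii = rng.uniform(*spec.mie_radius_range_um, size=(rows, cols))
        ns = rng.uniform(*spec.mie_n_range, size=(rows, cols))
        tr, tc = np.nonzero(tissue)
        for r, c in zip(tr, tc):
            cube[r, c] += spec.mie_fraction * mie_extinction(nu, radii[r, c], ns[r, c])
    if spec.noise_sigma > 0:
        cube += rng.normal(0.0, spec.noise_sigma, size=cube.shape)

    # planted defects on tissue pixels
    tissue_flat = np.nonzero(tissue.reshape(-1))[0]
    n_defects = spec.n_blank + spec.n_saturated
    if n_defects > tissue_flat.size:
        raise ParameterError("more defects requested than tissue pixels")
    defect_idx = rng.choice(tissue_flat, size=n_defects, replace=False)
    blank_idx, sat_idx = defect_idx[: spec.n_blank], defect_idx[spec.n_blank :]
    flat_cube = cube.reshape(-1, nu.size)
    flat_cube[blank_idx] = 0.0
    flat_cube[sat_idx] *= spec.saturation_factor

    truth_labels = labels.copy()
    truth_labels.reshape(-1)[defect_idx] = 0  # defects excluded from class truth
    concentration.reshape(-1)[defect_idx] = 0.0

    palette = {"epithelioid": "#1f77b4", "sarcomatoid": "#2ca02c", "stroma": "#bcbd22"}
    legend = {
        lbl: (name, palette.get(name, "#7f7f7f")) for name, lbl in name_to_label.items()
    }
    truth_map = LabelMap(labels=truth_labels, legend=legend)
    image = SpectralImage(
        cube=cube,
        axis=axis,
        pixel_size=pixel_size,
        stage_origin=stage_origin,
    )
    meta = {
        "blank_pixels": [divmod(int(i), cols) for i in blank_idx],
        "saturated_pixels": [divmod(int(i), cols) for i in sat_idx],
        "class_labels": name_to_label,
        "seed": spec.seed,
    }
    return image, truth_map, concentration, meta


def generate_reference_points(
    true_transform: HelmertTransform,
    n: int = 3,
    noise_sigma: float = 0.0,
    seed: int = 0,
    extent_um: float = 1000.0,
) -> ReferencePointSet:
    """Fiducial pairs: random sources, destinations = transform + noise.

    Sources are drawn uniformly in a square of side ``extent_um`` and
    redrawn until non-collinear, so the set is always estimable.
    """
    if n < 3:
        raise ParameterError("need at least 3 reference points")
    rng = np.random.default_rng(seed)
    from .roi_transfer import apply_helmert

    for _ in range(100):
        src = rng.uniform(0, extent_um, size=(n, 2))
        dst = apply_helmert(true_transform, src)
        if noise_sigma > 0:
            dst = dst + rng.normal(0.0, noise_sigma, size=dst.shape)
        points = ReferencePointSet(
            [(tuple(s), tuple(d)) for s, d in zip(src, dst)]
        )
        try:
            points.require_estimable(tol=1e-3)
        except Exception:
            continue
        return points
    raise RuntimeError("failed to draw a non-collinear reference set")


def generate_protein_table(
    n_proteins: int = 200,
    n_a: int = 6,
    n_b: int = 4,
    replicates: int = 3,
    n_de: int = 20,
    signed_effect: float = 4.0,
    cv: float = 0.10,
    frac_two_peptides: float = 0.8,
    group_names: tuple[str, str] = ("epithelioid", "sarcomatoid"),
    seed: int = 0,
    accessions: list[str] | None = None,
) -> tuple[ProteinAbundanceTable, pd.DataFrame]:
    """Log-normal protein table with planted group effects; returns truth.

    The first ``n_de`` proteins carry a multiplicative effect: abundance in
    group A is ``|signed_effect|`` times higher (or lower, for a negative
    sign) than in group B.  Technical replicates add log-normal noise at the
    stated coefficient of variation; biological samples add half that
    spread.  Unique-peptide counts are >=1 with the stated fraction >=2.
    """
    if n_de > n_proteins:
        raise ParameterError("n_de cannot exceed n_proteins")
    if cv < 0 or abs(signed_effect) < 1 and n_de > 0:
        raise ParameterError("cv must be >=0 and |signed_effect| >= 1")
    rng = np.random.default_rng(seed)
    if accessions is None:
        accessions = [f"SYN{i:05d}" for i in range(n_proteins)]
    elif len(accessions) != n_proteins:
        raise ParameterError("accessions length must equal n_proteins")

    base = rng.lognormal(mean=np.log(1e4), sigma=1.0, size=n_proteins)
    effect = np.ones(n_proteins)
    signs = np.empty(n_proteins, dtype=object)
    de_mask = np.zeros(n_proteins, dtype=bool)
    de_mask[:n_de] = True
    for i in range(n_de):
        if signed_effect >= 0:
            effect[i] = abs(signed_effect)
            signs[i] = f"{group_names[0]}-higher"
        else:
            effect[i] = 1.0 / abs(signed_effect)
            signs[i] = f"{group_names[1]}-higher"

    sigma_rep = np.sqrt(np.log1p(cv**2))
    sigma_bio = sigma_rep / 2.0
    samples = [(f"A{i+1}", group_names[0]) for i in range(n_a)] + [
        (f"B{i+1}", group_names[1]) for i in range(n_b)
    ]
    columns: dict[str, np.ndarray] = {}
    design_rows = []
    for sample, group in samples:
        group_scale = effect if group == group_names[0] else np.ones(n_proteins)
        bio = rng.lognormal(mean=0.0, sigma=sigma_bio, size=n_proteins)
        sample_mean = base * group_scale * bio
        for rep in range(1, replicates + 1):
            run = f"{sample}_r{rep}"
            noise = rng.lognormal(mean=0.0, sigma=sigma_rep, size=n_proteins)
            columns[run] = sample_mean * noise
            design_rows.append({"run": run, "sample": sample, "group": group, "replicate": rep})

    peptides = np.where(
        rng.random(n_proteins) < frac_two_peptides,
        rng.integers(2, 11, size=n_proteins),
        1,
    )
    proteins = pd.DataFrame(
        {
            "accession": accessions,
            "gene": [f"GENE{i}" for i in range(n_proteins)],
            "unique_peptides": peptides,
        }
    )
    table = ProteinAbundanceTable(
        proteins=proteins,
        abundances=pd.DataFrame(columns),
        design=pd.DataFrame(design_rows),
    )
    truth = pd.DataFrame(
        {
            "accession": accessions,
            "planted": de_mask,
            "true_ratio_a_over_b": np.where(de_mask, effect, 1.0),
            "direction": [signs[i] if de_mask[i] else "" for i in range(n_proteins)],
        }
    )
    return table, truth


def load_marker_panel() -> pd.DataFrame:
    """Published mesothelioma marker panel (nine proteins) with p-value,
    fold change and printed Euclidean ranking distance."""
    with resources.files("ftirlcm.data").joinpath("dmm_marker_panel.csv").open() as fh:
        return pd.read_csv(fh)
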