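"""Synthetic mountain scenes: DSM + 4-band image + ground-truth labels.

The generator produces a scene with an east-west ridgeline, a north and a
south slope, belt-structured vegetation classes drawn from a
:class:`~mabveg.mab_model.MabTable`, class-specific spectral signatures,
fuzzy belt boundaries and additive band noise, so the whole sampling and
classification pipeline can be exercised without satellite data.

Band order throughout: Blue, Green, Red, NIR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .mab_model import MabTable, default_mab_table

__all__ = [
    "BANDS",
    "NODATA",
    "NONVEG",
    "CULTIVATED",
    "SpectralSignature",
    "SceneParams",
    "SceneBundle",
    "default_signatures",
    "separable_signatures",
    "scene_class_names",
    "synth_dsm",
    "synth_truth",
    "synth_image",
    "generate_scene",
]

BANDS = ("blue", "green", "red", "nir")

# Fixed label codes; vegetation formations are numbered 3.. in legend order.
NODATA = 0
NONVEG = 1
CULTIVATED = 2

NONVEG_NAME = "non-vegetation"
CULTIVATED_NAME = "cultivated plants"


@dataclass(frozen=True)
class SpectralSignature:
    """Per-class band means/noise; mixtures carry the two parent mean vectors."""

    formation: str
    band_means: tuple[float, float, float, float]
    band_sd: tuple[float, float, float, float] = (3.0, 3.0, 3.0, 3.0)
    textured: bool = False
    mix_means: tuple[tuple, tuple] | None = None  # pixel-level 2-endmember mixture
    mix_fraction: float = 0.5

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.band_means):
            raise ValueError(f"{self.formation}: band means must be >= 0")

    def effective_means(self) -> np.ndarray:
        """Expected per-band means (mixture expectation for mixed classes)."""
        if self.mix_means is not None:
            a, b = (np.asarray(m, float) for m in self.mix_means)
            return self.mix_fraction * a + (1.0 - self.mix_fraction) * b
        return np.asarray(self.band_means, float)

    @property
    def ndvi(self) -> float:
        m = self.effective_means()
        return float((m[3] - m[2]) / (m[3] + m[2]))


def default_signatures(table: MabTable | None = None) -> dict[str, SpectralSignature]:
    """Default signature set covering every class of the packaged belt table.

    Conifer classes are brighter in NIR and carry a texture flag; mixed-forest
    classes are pixel-level mixtures of their parent signatures; the
    non-vegetation signature satisfies NDVI*100 < -2.
    """
    betula = (38.0, 46.0, 35.0, 115.0)
    pinus = (30.0, 40.0, 28.0, 135.0)
    betula_sept = (45.0, 52.0, 30.0, 108.0)
    sigs = [
        SpectralSignature(NONVEG_NAME, (120.0, 120.0, 115.0, 110.0)),
        SpectralSignature(CULTIVATED_NAME, (52.0, 60.0, 48.0, 90.0)),
        SpectralSignature("Quercus variabilis forest", (48.0, 52.0, 50.0, 72.0)),
        SpectralSignature("Quercus aliena var. acuteserrata forest", (42.0, 48.0, 40.0, 95.0)),
        SpectralSignature("Quercus liaotungensis forest", (40.0, 45.0, 36.0, 105.0)),
        SpectralSignature(
            "mixed forests of Betula albosinensis with Pinus armandii",
            tuple((np.add(betula, pinus) / 2).tolist()),
            textured=True,
            mix_means=(betula, pinus),
        ),
        SpectralSignature("Betula albosinensis var. septentrionalis forest", betula_sept),
        SpectralSignature(
            "mixed forests of Betula albosinensis with Betula albosinensis var. septentrionalis",
            tuple((np.add(betula, betula_sept) / 2).tolist()),
            mix_means=(betula, betula_sept),
        ),
        SpectralSignature("Abies fargesii forest", (28.0, 38.0, 26.0, 140.0), textured=True),
        SpectralSignature("Larix chinensis forest", (26.0, 35.0, 24.0, 150.0), textured=True),
        SpectralSignature("subalpine shrub and meadow", (48.0, 58.0, 38.0, 112.0)),
    ]
    out = {s.formation: s for s in sigs}
    nv = out[NONVEG_NAME]
    assert nv.ndvi * 100 < -2, "non-vegetation signature must satisfy NDVI*100 < -2"
    return out


def separable_signatures(table: MabTable | None = None) -> dict[str, SpectralSignature]:
    """A strongly separated signature set for noiseless sanity scenes.

    Every pair of classes adjacent along the belt sequence differs so much
    spectrally that, on a noiseless scene, no cross-class region merge is
    ever cheaper than a small segmentation threshold - which makes a
    pixel-perfect end-to-end run achievable.
    """
    sigs = [
        SpectralSignature(NONVEG_NAME, (180.0, 180.0, 175.0, 165.0)),
        SpectralSignature(CULTIVATED_NAME, (110.0, 115.0, 100.0, 160.0)),
        SpectralSignature("Quercus variabilis forest", (20.0, 30.0, 15.0, 120.0)),
        SpectralSignature("Quercus aliena var. acuteserrata forest", (70.0, 85.0, 60.0, 185.0)),
        SpectralSignature("Quercus liaotungensis forest", (15.0, 25.0, 10.0, 125.0)),
        SpectralSignature(
            "mixed forests of Betula albosinensis with Pinus armandii",
            (25.0, 95.0, 15.0, 240.0), textured=True,
        ),
        SpectralSignature("Betula albosinensis var. septentrionalis forest", (25.0, 35.0, 20.0, 130.0)),
        SpectralSignature(
            "mixed forests of Betula albosinensis with Betula albosinensis var. septentrionalis",
            (85.0, 30.0, 70.0, 140.0),
        ),
        SpectralSignature("Abies fargesii forest", (80.0, 95.0, 70.0, 235.0), textured=True),
        SpectralSignature("Larix chinensis forest", (20.0, 28.0, 12.0, 150.0), textured=True),
        SpectralSignature("subalpine shrub and meadow", (85.0, 100.0, 75.0, 240.0)),
    ]
    out = {s.formation: s for s in sigs}
    assert out[NONVEG_NAME].ndvi * 100 < -2
    return out


def scene_class_names(table: MabTable | None = None) -> tuple[str, ...]:
    """Ordered class legend: no-data, non-vegetation, cultivated, formations."""
    table = table or default_mab_table()
    names = ["no-data", NONVEG_NAME, CULTIVATED_NAME]
    for slope in ("north", "south"):
        for f in table.formations(slope):
            if f not in names:
                names.append(f)
    return tuple(names)


@dataclass(frozen=True)
class SceneParams:
    rows: int = 512
    cols: int = 512
    pixel_size: float = 10.0
    base_elev: float = 500.0
    peak_elev: float = 3771.2
    ridge_row: int | None = None  # default rows // 2
    perturb_amp: float = 250.0
    perturb_scale: float = 8.0
    boundary_sigma: float = 40.0
    boundary_corr: float = 10.0
    band_sd_scale: float = 1.0
    field_amp: float = 0.06
    field_corr: float = 20.0
    texture_amp: float = 0.08
    pixel_mix: bool = True
    cultivated_fraction: float = 0.6
    seed: int = 0

    @property
    def ridge(self) -> int:
        return self.rows // 2 if self.ridge_row is None else self.ridge_row


@dataclass
class SceneBundle:
    """A complete synthetic scene plus everything needed to reproduce it."""

    dsm: np.ndarray  # (rows, cols) metres
    image: np.ndarray  # (4, rows, cols) DN
    truth: np.ndarray  # (rows, cols) int16 class ids
    class_names: tuple[str, ...]
    params: SceneParams
    signatures: dict[str, SpectralSignature] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.dsm.shape == self.truth.shape == self.image.shape[1:]):
            raise ValueError("dsm, image and truth must share one grid")

    def class_id(self, name: str) -> int:
        return self.class_names.index(name)

    def save(self, outdir: str | Path) -> None:
        """Write dsm/image/truth as TIFF plus a JSON provenance sidecar."""
        import tifffile

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(outdir / "dsm.tif", self.dsm.astype(np.float32),
                         photometric="minisblack")
        tifffile.imwrite(outdir / "image.tif", self.image.astype(np.float32),
                         photometric="minisblack")
        tifffile.imwrite(outdir / "truth.tif", self.truth.astype(np.int16),
                         photometric="minisblack")
        meta = {
            "params": asdict(self.params),
            "class_names": list(self.class_names),
            "bands": list(BANDS),
        }
        (outdir / "scene.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def synth_dsm(
    rows: int,
    cols: int,
    base_elev: float,
    peak_elev: float,
    ridge_row: int,
    seed: int,
    perturb_amp: float = 30.0,
    perturb_scale: float = 15.0,
) -> np.ndarray:
    """Ridge-shaped DSM: elevation falls off monotonically away from ridge_row.

    A smooth seeded perturbation, tapered to zero at the ridge, roughens the
    flanks; the maximum elevation is exactly ``peak_elev`` on the ridge row.
    """
    if rows <= 0 or cols <= 0:
        raise ValueError("rows and cols must be positive")
    if not peak_elev > base_elev:
        raise ValueError("peak_elev must exceed base_elev")
    if not 0 <= ridge_row < rows:
        raise ValueError("ridge_row out of range")
    if not perturb_amp < peak_elev - base_elev:
        raise ValueError("perturb_amp must be smaller than the total relief")

    dist = np.abs(np.arange(rows) - ridge_row).astype(float)
    max_dist = max(dist.max(), 1.0)
    drop_per_row = (peak_elev - base_elev) / max_dist
    profile = peak_elev - drop_per_row * dist
    dsm = np.tile(profile[:, None], (1, cols))
    if perturb_amp > 0:
        rng = np.random.default_rng(seed)
        noise = gaussian_filter(rng.standard_normal((rows, cols)), perturb_scale)
        peak_abs = np.abs(noise).max()
        if peak_abs > 0:
            noise /= peak_abs
        # short ramp keeps the ridge row the per-column maximum: within the
        # ramp the perturbation stays below 80% of the per-row drop
        ramp = min(max_dist, 1.25 * perturb_amp / drop_per_row)
        taper = np.minimum(dist / max(ramp, 1.0), 1.0)[:, None]
        dsm = dsm + perturb_amp * noise * taper
    return dsm


def _belt_index_raster(
    elev: np.ndarray, north_mask: np.ndarray, table: MabTable
) -> np.ndarray:
    """Per-pixel index into the slope's belt list (-1 where outside the table)."""
    idx = np.full(elev.shape, -1, dtype=np.int32)
    for slope, mask in (("north", north_mask), ("south", ~north_mask)):
        belts = table.slope_belts(slope)
        edges = np.array([b.alt_lo for b in belts] + [belts[-1].alt_hi])
        e = elev[mask]
        j = np.searchsorted(edges, e, side="right") - 1
        j[e == edges[-1]] = len(belts) - 1  # summit belt closed at the top
        j[(e < edges[0]) | (e > edges[-1])] = -1
        idx[mask] = j
    return idx


def synth_truth(
    dsm: np.ndarray,
    ridge_row: int,
    table: MabTable,
    boundary_sigma: float,
    seed: int,
    class_names: tuple[str, ...] | None = None,
    cultivated_fraction: float = 0.6,
    boundary_corr: float = 10.0,
) -> np.ndarray:
    """Ground-truth labels: belt membership of (elevation + boundary noise).

    The boundary noise is a Normal(0, boundary_sigma) elevation displacement;
    with ``boundary_corr > 0`` it is spatially correlated (smooth), so belt
    boundaries undulate coherently and whole patches - not individual pixels -
    cross into neighbouring belts.  Rows with index <= ridge_row are the
    north slope.  Pixels in the basal belt are split into cultivated plants /
    non-vegetation by thresholding a smooth seeded field at
    ``cultivated_fraction``.  DSM above the table summit is no-data.
    """
    if boundary_sigma < 0:
        raise ValueError("boundary_sigma must be >= 0")
    class_names = class_names or scene_class_names(table)
    rng = np.random.default_rng(seed)
    rows, cols = dsm.shape
    north = (np.arange(rows) <= ridge_row)[:, None] & np.ones((1, cols), bool)

    elev = dsm.astype(float)
    if boundary_sigma > 0:
        eps = rng.standard_normal(dsm.shape)
        if boundary_corr > 0:
            eps = gaussian_filter(eps, boundary_corr)
            sd = eps.std()
            if sd > 0:
                eps /= sd
        elev = elev + boundary_sigma * eps
    # keep boundary noise from pushing pixels off the table
    summit = min(table.summit("north"), table.summit("south"))
    elev = np.clip(elev, 0.0, summit)
    elev[dsm > max(table.summit("north"), table.summit("south"))] = np.inf

    idx = _belt_index_raster(elev, north, table)
    truth = np.full(dsm.shape, NODATA, dtype=np.int16)
    name_to_id = {n: i for i, n in enumerate(class_names)}
    for slope, mask in (("north", north), ("south", ~north)):
        belts = table.slope_belts(slope)
        for j, belt in enumerate(belts):
            sel = mask & (idx == j)
            if belt.formation == table.basal_formation:
                truth[sel] = -1  # placeholder, split below
            else:
                truth[sel] = name_to_id[belt.formation]

    basal = truth == -1
    if basal.any():
        fld = gaussian_filter(rng.standard_normal(dsm.shape), 8.0)
        cut = np.quantile(fld[basal], cultivated_fraction)
        truth[basal & (fld <= cut)] = CULTIVATED
        truth[basal & (fld > cut)] = NONVEG
    return truth


def synth_image(
    truth: np.ndarray,
    signatures: dict[str, SpectralSignature],
    seed: int,
    class_names: tuple[str, ...] | None = None,
    band_sd_scale: float = 1.0,
    texture_amp: float = 0.08,
    pixel_mix: bool = True,
    field_amp: float = 0.0,
    field_corr: float = 20.0,
) -> np.ndarray:
    """Render a 4-band image from labels and signatures (noise clipped at 0).

    ``field_amp > 0`` adds a smooth multiplicative "condition" field (stand
    vigour / illumination surrogate) so that within-class reflectance varies
    coherently across the scene and overlaps neighbouring-class levels.
    """
    class_names = class_names or scene_class_names()
    rng = np.random.default_rng(seed)
    rows, cols = truth.shape
    image = np.zeros((4, rows, cols), float)
    cond = None
    if field_amp > 0:
        fld = gaussian_filter(rng.standard_normal((rows, cols)), field_corr)
        sd = fld.std()
        if sd > 0:
            fld /= sd
        cond = 1.0 + field_amp * fld

    present = np.unique(truth)
    texture = None
    for cid in present:
        if cid == NODATA:
            continue
        name = class_names[cid]
        sig = signatures.get(name)
        if sig is None:
            raise KeyError(f"no spectral signature for label {name!r} (id {cid})")
        mask = truth == cid
        n = int(mask.sum())
        if sig.mix_means is not None and pixel_mix:
            pick = rng.random(n) < sig.mix_fraction
            a, b = (np.asarray(m, float) for m in sig.mix_means)
            base = np.where(pick[:, None], a[None, :], b[None, :])
        else:
            base = np.broadcast_to(sig.effective_means(), (n, 4)).copy()
        sd = np.asarray(sig.band_sd, float) * band_sd_scale
        if np.any(sd > 0):
            base = base + rng.normal(0.0, 1.0, (n, 4)) * sd
        vals = base.T  # (4, n)
        if cond is not None:
            vals = vals * cond[mask][None, :]
        if sig.textured and texture_amp > 0:
            if texture is None:
                raw = rng.standard_normal((rows, cols))
                texture = raw - gaussian_filter(raw, 2.0)  # high-pass pattern
            vals = vals * (1.0 + texture_amp * texture[mask][None, :])
        for b_i in range(4):
            image[b_i][mask] = vals[b_i]
    return np.clip(image, 0.0, None)


def generate_scene(
    params: SceneParams = SceneParams(),
    table: MabTable | None = None,
    signatures: dict[str, SpectralSignature] | None = None,
) -> SceneBundle:
    """Full seeded scene: child seeds are split off params.seed deterministically."""
    table = table or default_mab_table()
    signatures = signatures or default_signatures(table)
    class_names = scene_class_names(table)
    s_dsm, s_truth, s_img = np.random.SeedSequence(params.seed).spawn(3)

    dsm = synth_dsm(
        params.rows,
        params.cols,
        params.base_elev,
        params.peak_elev,
        params.ridge,
        seed=np.random.default_rng(s_dsm).integers(2**31),
        perturb_amp=params.perturb_amp,
        perturb_scale=params.perturb_scale,
    )
    truth = synth_truth(
        dsm,
        params.ridge,
        table,
        params.boundary_sigma,
        seed=np.random.default_rng(s_truth).integers(2**31),
        class_names=class_names,
        cultivated_fraction=params.cultivated_fraction,
        boundary_corr=params.boundary_corr,
    )
    image = synth_image(
        truth,
        signatures,
        seed=np.random.default_rng(s_img).integers(2**31),
        class_names=class_names,
        band_sd_scale=params.band_sd_scale,
        texture_amp=params.texture_amp,
        pixel_mix=params.pixel_mix,
        field_amp=params.field_amp,
        field_corr=params.field_corr,
    )
    return SceneBundle(
        dsm=dsm,
        image=image,
        truth=truth,
        class_names=class_names,
        params=params,
        signatures=signatures,
    )
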