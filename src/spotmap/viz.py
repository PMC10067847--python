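"""Rendering of probabilistic maps and result export."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .mpm import MPMResult

__all__ = ["render_map", "export_result", "contours_to_geojson"]

HOTSPOT_COLORS = ("red", "white")
COLDSPOT_COLORS = ("blue", "white")


def render_map(result: MPMResult, out) -> None:
    """Density raster with hotspot (red/white) and coldspot (blue/white) contours.

    A JSON sidecar next to the image records the color legend and the run
    parameters.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(result.density.values, origin="upper", cmap="viridis")
    fig.colorbar(im, ax=ax, shrink=0.8, label="sum-normalized density")
    for polys, (outer, inner) in (
        (result.hotspots, HOTSPOT_COLORS),
        (result.coldspots, COLDSPOT_COLORS),
    ):
        for poly in polys:
            ax.plot(poly[:, 0], poly[:, 1], color=outer, lw=1.8)
            ax.plot(poly[:, 0], poly[:, 1], color=inner, lw=0.6)
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title(f"h={result.bandwidth:g} px, alpha={result.alpha:g}")
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    sidecar = Path(str(out)).with_suffix(".legend.json")
    sidecar.write_text(
        json.dumps(
            {
                "hotspot_contour_colors": list(HOTSPOT_COLORS),
                "coldspot_contour_colors": list(COLDSPOT_COLORS),
                "bandwidth_px": result.bandwidth,
                "alpha": result.alpha,
                "seed": result.seed,
            },
            indent=2,
        )
    )


def contours_to_geojson(polygons) -> dict:
    """Polygons as a GeoJSON FeatureCollection in pixel coordinates."""
    feats = []
    for poly in polygons:
        ring = np.asarray(poly, float)
        if ring.size and not np.array_equal(ring[0], ring[-1]):
            ring = np.vstack([ring, ring[0]])
        feats.append(
            {
                "type": "Feature",
                "properties": {},
                "geometry": {"type": "Polygon", "coordinates": [ring.tolist()]},
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def export_result(result: MPMResult, outdir) -> None:
    """Write density/p-value rasters, contours and a reproducibility manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.save(outdir / "density.npy", result.density.values)
    np.save(outdir / "csr_density.npy", result.csr_density.values)
    np.save(outdir / "p_upr_adj.npy", result.pvals.p_upr_adj.values)
    np.save(outdir / "p_lwr_adj.npy", result.pvals.p_lwr_adj.values)
    np.save(outdir / "hotspot_mask.npy", result.hotspot_mask)
    np.save(outdir / "coldspot_mask.npy", result.coldspot_mask)
    (outdir / "hotspots.geojson").write_text(
        json.dumps(contours_to_geojson(result.hotspots))
    )
    (outdir / "coldspots.geojson").write_text(
        json.dumps(contours_to_geojson(result.coldspots))
    )
    h, w = result.density.values.shape
    (outdir / "manifest.json").write_text(
        json.dumps(
            {
                "grid": [h, w],
                "bandwidth_px": result.bandwidth,
                "alpha": result.alpha,
                "seed": result.seed,
                "mu_csr": result.pvals.mu_csr,
                "sigma_csr": result.pvals.sigma_csr,
                "n_points": result.spp.n if result.spp is not None else None,
                "hotspot_fraction": result.hotspot_fraction(),
                "coldspot_fraction": result.coldspot_fraction(),
            },
            indent=2,
        )
    )
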