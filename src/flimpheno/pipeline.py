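"""High-level convenience: simulated dataset -> per-cell feature table."""

from __future__ import annotations

from .features import aggregate_features, merge_tables
from .fitting import FitConfig, fit_image
from .phasor import phasor_image
from .synthetic import SimulatedDataset

__all__ = ["extract_feature_table"]


def extract_feature_table(
    dataset: SimulatedDataset,
    irf,
    fit_config: FitConfig | None = None,
    min_valid_pixels: int = 10,
):
    """Run both quantification routes on every field and aggregate per cell.

    Fits each channel per pixel, computes the calibrated phasor maps with the
    same binning and photon threshold, and returns the merged 12-feature table
    with the phenotype name as the group label.
    """
    fit_config = fit_config or FitConfig()
    tables = []
    for fld in dataset.fields:
        fit_n = fit_image(fld.nadph, irf, fit_config)
        fit_f = fit_image(fld.fad, irf, fit_config)
        ph_n = phasor_image(fld.nadph, irf, spatial_bin=fit_config.spatial_bin,
                            min_photons=fit_config.min_photons)
        ph_f = phasor_image(fld.fad, irf, spatial_bin=fit_config.spatial_bin,
                            min_photons=fit_config.min_photons)
        tables.append(
            aggregate_features(
                fit_n, fit_f, ph_n, ph_f, fld.mask, group=fld.phenotype,
                field_id=fld.field_id, min_valid_pixels=min_valid_pixels,
            )
        )
    return merge_tables(tables)
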