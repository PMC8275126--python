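"""Bundled simulation presets: 30-min-frame onset cohorts for medaka and
zebrafish organoids and embryos, a morphometry image preset, and a
15-min-frame migration preset whose regime switch falls at 34 h
post-aggregation (10 h into a movie starting at 24 hpa).
"""

from __future__ import annotations

from .config import SimConfig

__all__ = ["PRESETS", "get_preset", "MIGRATION_T0_HPA"]

# the migration movie starts at 24 h post-aggregation; simulated times are
# relative to movie start, so add this offset to report hpa
MIGRATION_T0_HPA = 24.0

_ONSET_COMMON = dict(frame_interval_min=30.0, duration_h=20.0, rise_time_h=2.0, noise_sd=0.02, baseline=0.05)

PRESETS: dict[str, SimConfig] = {
    "medaka-onset": SimConfig.from_dict(
        # rise 1.5 h keeps onset_mean + 3*rise within the 20 h acquisition
        {
            "cohort": dict(
                n_traces=17,
                onset_mean_h=15.5,
                onset_sd_h=0.36,
                frame_interval_min=30.0,
                duration_h=20.0,
                rise_time_h=1.5,
                noise_sd=0.02,
                baseline=0.05,
            )
        }
    ),
    "medaka-embryo-onset": SimConfig.from_dict(
        {"cohort": dict(n_traces=6, onset_mean_h=13.5, onset_sd_h=1.03, **_ONSET_COMMON)}
    ),
    "zebrafish-onset": SimConfig.from_dict(
        {
            "cohort": dict(
                n_traces=15,
                onset_mean_h=9.75,
                onset_sd_h=0.21,
                frame_interval_min=30.0,
                duration_h=18.0,
                rise_time_h=2.0,
                noise_sd=0.02,
                baseline=0.05,
            )
        }
    ),
    "zebrafish-embryo-onset": SimConfig.from_dict(
        {
            "cohort": dict(
                n_traces=6,
                onset_mean_h=7.88,
                onset_sd_h=0.77,
                frame_interval_min=30.0,
                duration_h=18.0,
                rise_time_h=2.0,
                noise_sd=0.02,
                baseline=0.05,
            )
        }
    ),
    "morphometry": SimConfig.from_dict(
        {
            "image": dict(
                size_px=512,
                pixel_size_um=1.0,
                organoid_radius_um=150.0,
                n_domains=2,
                domain_radius_um=40.0,
                fg_intensity=200.0,
                bg_intensity=40.0,
                noise_sd=5.0,
                min_domain_gap_um=10.0,
            )
        }
    ),
    "migration": SimConfig.from_dict(
        {
            "tracks": dict(
                n_cells=4600,
                aggregate_radius_um=300.0,
                D_um2_per_min=0.5,
                v_um_per_min=0.45,
                p_outward=0.51,
                t_switch_h=10.0,
                duration_h=16.0,
                dt_min=15.0,
                loc_noise_um=0.5,
                miss_rate=0.0,
            ),
            "image": dict(size_px=512, pixel_size_um=1.0, organoid_radius_um=300.0),
        }
    ),
}

# cohort onset_sd_h values take the reported "mean +/- x" spread as the
# cohort standard deviation


def get_preset(name: str, seed: int = 0) -> SimConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name].replace(seed=seed)
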