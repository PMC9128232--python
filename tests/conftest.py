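import numpy as np

from circarun.io import WheelRecording


def make_recording(
    counts,
    bin_minutes=1,
    condition="LD",
    subject_id="s1",
    t0_offset_minutes=0.0,
    **kw,
):
    """Build a WheelRecording with sensible defaults for tests."""
    return WheelRecording(
        subject_id=subject_id,
        genotype=kw.pop("genotype", "custom"),
        sex=kw.pop("sex", "F"),
        age_group=kw.pop("age_group", "young"),
        condition=condition,
        counts=np.asarray(counts),
        bin_minutes=bin_minutes,
        lights_on_clock="07:00" if condition == "LD" else None,
        t0_offset_minutes=t0_offset_minutes,
        **kw,
    )


def cosine_series(mesor, amplitude, acrophase_hours, tau_hours, n_days,
                  bin_minutes=1, noise_sd=0.0, seed=0):
    """Cosine series on bin midpoints, optionally with Gaussian noise."""
    n = n_days * 1440 // bin_minutes
    t = (np.arange(n) + 0.5) * bin_minutes / 60.0
    y = mesor + amplitude * np.cos(2 * np.pi * (t - acrophase_hours) / tau_hours)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, n)
    return y
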