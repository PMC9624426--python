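"""Generator for optomotor-response trials.

Each trial is a distance-to-centre trace at 30 frames/s: 20 s of
concentric rings drifting toward the dish centre, during which the fish
drifts centerward at ``attraction`` mm/s (plus noise), followed by a
20-s refractory period with mild outward drift. When ``n_trials`` is not
given, the per-fish trial count is drawn uniformly from [46, 59], the
range presented over a one-hour session.
"""

from __future__ import annotations

import numpy as np

from ..behavior import OptomotorTrial

__all__ = ["gen_optomotor"]


def gen_optomotor(attraction: float, n_trials: int | None = None,
                  seed: int = 0, *, start_radius: float = 30.0,
                  dish_radius: float = 50.0, noise_sd: float = 0.0,
                  outward_drift: float = 0.3, fps: float = 30.0,
                  stimulus_s: float = 20.0, refractory_s: float = 20.0
                  ) -> list[OptomotorTrial]:
    """Simulate optomotor trials; deterministic in ``seed``.

    ``attraction`` is the centerward drift speed (mm/s) during the
    stimulus; ``noise_sd`` the per-frame positional noise in mm.
    """
    if attraction < 0:
        raise ValueError("attraction must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    if n_trials is None:
        n_trials = int(rng.integers(46, 60))
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    n_stim = int(round(stimulus_s * fps))
    n_refr = int(round(refractory_s * fps))
    trials = []
    for _ in range(n_trials):
        r = np.empty(n_stim + n_refr + 1)
        r[0] = start_radius
        for f in range(1, len(r)):
            drift = -attraction / fps if f <= n_stim else outward_drift / fps
            r[f] = r[f - 1] + drift + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            r[f] = min(max(r[f], 0.0), dish_radius)
        trials.append(OptomotorTrial(distance_to_center=r,
                                     stimulus_window=(0.0, stimulus_s),
                                     fps=fps))
    return trials
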