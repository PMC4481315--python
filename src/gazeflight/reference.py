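"""Published per-bird wingbeat-mode mixture parameters for the lovebird cohort.

Reported two-component Gaussian-mixture fits (mean, SD per component) of
the instantaneous flapping frequency (Hz) and of the downstroke/upstroke
period ratio for the five birds of the U-turn study (ids 2dg, 2lg, 2y,
1y, 3g).  Component weights were not reported; the distributions are
plotted balanced, so 0.5/0.5 is assumed where a weight is needed.

These parameters are worked-example inputs: feeding them through
:func:`gazeflight.wingbeat_modes.cross_bird_mode_summary` reproduces the
published cohort numbers (normal-mode frequency 17.01 +- 0.87 Hz,
intermittent 9.58 +- 0.48 Hz, frequency separator 13.3 Hz, ratio
separator 0.94, ratio means 0.53 and 1.35).
"""

from __future__ import annotations

from .wingbeat_modes import GMMFit

#: bird id -> metric -> reported mixture fit (balanced weights assumed)
REFERENCE_MODE_FITS: dict[str, dict[str, GMMFit]] = {
    "2dg": {
        "frequency": GMMFit(mu1=9.78, sigma1=1.61, mu2=17.26, sigma2=1.01, xi1=0.5, xi2=0.5),
        "ratio": GMMFit(mu1=0.50, sigma1=0.07, mu2=1.26, sigma2=0.27, xi1=0.5, xi2=0.5),
    },
    "2lg": {
        "frequency": GMMFit(mu1=10.26, sigma1=1.83, mu2=18.14, sigma2=0.91, xi1=0.5, xi2=0.5),
        "ratio": GMMFit(mu1=0.56, sigma1=0.13, mu2=1.43, sigma2=0.17, xi1=0.5, xi2=0.5),
    },
    "2y": {
        "frequency": GMMFit(mu1=9.39, sigma1=1.10, mu2=17.19, sigma2=0.86, xi1=0.5, xi2=0.5),
        "ratio": GMMFit(mu1=0.48, sigma1=0.07, mu2=1.26, sigma2=0.27, xi1=0.5, xi2=0.5),
    },
    "1y": {
        "frequency": GMMFit(mu1=8.97, sigma1=0.60, mu2=15.76, sigma2=0.96, xi1=0.5, xi2=0.5),
        "ratio": GMMFit(mu1=0.62, sigma1=0.09, mu2=1.49, sigma2=0.17, xi1=0.5, xi2=0.5),
    },
    "3g": {
        "frequency": GMMFit(mu1=9.49, sigma1=2.30, mu2=16.72, sigma2=1.00, xi1=0.5, xi2=0.5),
        "ratio": GMMFit(mu1=0.48, sigma1=0.12, mu2=1.30, sigma2=0.17, xi1=0.5, xi2=0.5),
    },
}
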