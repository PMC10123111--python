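"""Published benchmark dwell-time fits for DNA-repair proteins on tethered DNA.

Component lifetimes (s) and fractions from C-trap measurements of
fluorescently tagged repair proteins in nuclear extracts, both as observed
and after per-component photobleaching correction.  These serve as worked
inputs for :func:`kymotrace.kinetics.weighted_average_lifetime` and as
regression anchors: the fraction-weighted averages recompute the reported
summary lifetimes.
"""

from __future__ import annotations

__all__ = ["BENCHMARK_FITS", "weighted_averages"]

# protein/substrate -> {"observed": [(tau_s, fraction)], "corrected": [...]}
BENCHMARK_FITS: dict[str, dict[str, list[tuple[float, float]]]] = {
    "YFP-PARP1/nicked": {
        "observed": [(4.2, 1.0)],
        "corrected": [(5.2, 1.0)],
    },
    "eGFP-XPC/UV": {
        "observed": [(0.9, 0.67), (48.7, 0.33)],
        "corrected": [(0.9, 0.67), (227.0, 0.33)],
    },
    "tGFP-APE1/nicked": {
        "observed": [(0.3, 1.0)],
        "corrected": [(0.3, 1.0)],
    },
    "tGFP-Polb/nicked": {
        "observed": [(1.8, 1.0)],
        "corrected": [(2.0, 1.0)],
    },
    "mNeonGreen-DDB2-stable/UV": {
        "observed": [(1.7, 0.50), (13.5, 0.50)],
        "corrected": [(1.7, 0.50), (16.6, 0.50)],
    },
    "mNeonGreen-DDB2-transient/UV": {
        "observed": [(3.8, 0.24), (31.0, 0.76)],
        "corrected": [(4.0, 0.24), (54.4, 0.76)],
    },
    "HaloTag-DDB2/UV": {
        "observed": [(3.9, 0.43), (16.2, 0.33), (90.3, 0.24)],
        "corrected": [(4.0, 0.43), (17.1, 0.33), (132.2, 0.24)],
    },
    "eGFP-DDB1/UV": {
        "observed": [(1.8, 0.14), (7.3, 0.44), (60.9, 0.42)],
        "corrected": [(1.8, 0.14), (7.6, 0.44), (95.5, 0.42)],
    },
    "mNeonGreen-DDB2-K244E/UV": {
        "observed": [(0.7, 0.53), (16.9, 0.47)],
        "corrected": [(0.7, 0.53), (57.0, 0.47)],
    },
    "OGG1-eGFP-WT/8oxoG": {
        "observed": [(0.7, 0.51), (3.2, 0.49)],
        "corrected": [(0.7, 0.51), (3.3, 0.49)],
    },
    "OGG1-eGFP-K249Q/8oxoG": {
        "observed": [(7.7, 0.78), (42.9, 0.22)],
        "corrected": [(8.9, 0.78), (183.0, 0.22)],
    },
}


def weighted_averages() -> dict[str, dict[str, float]]:
    """Fraction-weighted average lifetime for every benchmark entry."""
    from .kinetics import weighted_average_lifetime

    return {
        name: {
            kind: weighted_average_lifetime(comps)
            for kind, comps in entry.items()
        }
        for name, entry in BENCHMARK_FITS.items()
    }
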