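"""Run-level configuration shared by all analysis stages."""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class AnalysisConfig:
    """Parameters that scale read depth into genome-wide quantities.

    genome_size_bp
        Haploid genome size used as the denominator for genome-equivalent
        coverage and abundance extrapolation.  The default is the 22-Gb
        loblolly pine genome the pipeline was designed around.
    n_chromosomes
        Haploid chromosome count (pine: 12) used for per-chromosome
        abundance columns.
    identity_thresholds
        The two alignment stringencies (permissive, strict) at which
        coverage maps are built.
    window_bp
        Window size for display histograms of per-base depth.
    """

    genome_size_bp: int = 22_000_000_000
    n_chromosomes: int = 12
    identity_thresholds: tuple[float, float] = (0.75, 0.99)
    rng_seed: int = 0
    window_bp: int = 50

    def __post_init__(self) -> None:
        if self.genome_size_bp <= 0:
            raise ValueError("genome_size_bp must be positive")
        if self.n_chromosomes <= 0:
            raise ValueError("n_chromosomes must be positive")
        lo, hi = self.identity_thresholds
        if not (0.0 < lo < hi <= 1.0):
            raise ValueError(
                "identity_thresholds must be strictly increasing fractions in (0, 1]"
            )
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")
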