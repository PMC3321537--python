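"""Shared numeric configuration for the MMTS stages."""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class ModelConfig:
    """Numeric knobs shared by distance construction, screening and validation.

    Parameters
    ----------
    zeta_floor:
        Lower bound on a Gram-Schmidt component's standard deviation ζ_q.
        A full-model fit whose ζ_q falls at or below this floor raises
        :class:`~mmts.errors.CollinearityError`; in orthogonal-array screening
        runs the offending component is instead dropped from the distance sum
        and the run flagged degenerate (small classes cannot support every
        feature subset at full rank).
    md_floor:
        Lower bound applied to own-class Mahalanobis distances when they
        appear as denominators in signal-to-noise ratios, to avoid division
        blow-ups from near-zero self distances.
    sn_exponent:
        Exponent on the between/own distance ratio inside the
        larger-the-better signal-to-noise ratio. 1 is the form the method
        defines; 2 is the textbook larger-the-better form.
    ratio_threshold:
        Abnormal-to-normal mean-distance ratio a class must exceed for the
        measurement scale to be declared valid. The method itself only asks
        for "much larger" abnormal distances; the threshold is this package's
        operational criterion and is reported as such.
    min_component_dof:
        Minimum residual degrees of freedom, n − 1 − (components already
        kept), a Gram-Schmidt component needs for its ζ_q estimate to be
        retained in subspace ('drop') fits. With k components already
        removed from a component's residual, ζ_q² is a variance estimated
        on n − 1 − k degrees of freedom; below ~3 the estimate collapses
        toward zero and a single out-of-sample example can dominate the
        distance. Ignored in 'error'-mode fits, which require full rank
        anyway.
    """

    zeta_floor: float = 1e-8
    md_floor: float = 1e-12
    sn_exponent: int = 1
    ratio_threshold: float = 2.0
    min_component_dof: int = 3

    def __post_init__(self) -> None:
        if self.zeta_floor <= 0 or self.md_floor <= 0:
            raise ValueError("zeta_floor and md_floor must be positive")
        if self.sn_exponent not in (1, 2):
            raise ValueError("sn_exponent must be 1 or 2")
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be positive")
        if self.min_component_dof < 1:
            raise ValueError("min_component_dof must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)
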