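"""Validated run configuration for end-to-end pipelines."""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field


class RunConfig(BaseModel):
    """Configuration for a full simulate-to-classify run.

    Unknown keys are rejected on load.
    """

    model_config = ConfigDict(extra="forbid")

    fs: float = Field(default=125.0, gt=0, description="sampling rate, Hz")
    wavelet: str = "db4"
    alpha: float = Field(default=0.5, ge=0.0, le=1.0,
                         description="compromise-shrinkage fraction")
    n_eff: int = Field(default=500, gt=1)
    amp_tol: float = Field(default=0.3, gt=0)
    period_tol: float = Field(default=0.25, gt=0)
    n_records: int = Field(default=1260, ge=4)
    slippery_frac: float = Field(default=0.29, gt=0.0, lt=1.0)
    n_cycles: int = Field(default=8, ge=1)
    baseline_amp: float = Field(default=3.0, ge=0)
    baseline_freq: float = Field(default=0.2, gt=0, lt=0.5)
    white_sd: float = Field(default=0.5, ge=0)
    corrupt_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    seed: int = 0
    comparison_seeds: tuple[int, ...] = (0, 1, 2)
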