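"""Time-series containers shared by every simulator, with CSV round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["Trajectory", "ResponseCurve"]


@dataclass
class Trajectory:
    """Sampled Cdk1 / APC/C time series produced by any simulator.

    Attributes
    ----------
    t : ndarray
        Sample times (min), strictly increasing.
    cdk1 : ndarray
        Cdk1 activity (nM), nonnegative.
    apc : ndarray
        APC/C activity, within [0, 1].
    events : list of (float, str)
        Optional switch records from the event-driven relay solver
        (kinds: ``cross_up``, ``cross_down``, ``apc_on``, ``apc_off``).
    tau : ndarray or None
        Instantaneous delay along the run (state-dependent model only).
    meta : dict
        Free-form annotations (e.g. ``oscillating`` flag from the relay solver).
    """

    t: np.ndarray
    cdk1: np.ndarray
    apc: np.ndarray
    events: list = field(default_factory=list)
    tau: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.cdk1 = np.asarray(self.cdk1, dtype=float)
        self.apc = np.asarray(self.apc, dtype=float)
        if self.t.ndim != 1 or len(self.t) != len(self.cdk1) or len(self.t) != len(self.apc):
            raise DomainError("t, cdk1 and apc must be 1-d arrays of equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise DomainError("sample times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t, "cdk1": self.cdk1, "apc": self.apc}
        if self.tau is not None:
            data["tau"] = self.tau
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def events_to_csv(self, path) -> None:
        pd.DataFrame(self.events, columns=["t", "kind"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        tau = df["tau"].to_numpy() if "tau" in df.columns else None
        return cls(t=df["t"].to_numpy(), cdk1=df["cdk1"].to_numpy(),
                   apc=df["apc"].to_numpy(), tau=tau)


@dataclass
class ResponseCurve:
    """A (time, activity) step-response curve, e.g. APC/C output after a Cdk1 jump."""

    t: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.ndim != 1 or len(self.t) != len(self.value):
            raise DomainError("t and value must be 1-d arrays of equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise DomainError("curve times must be strictly increasing")

    def to_csv(self, path) -> None:
        pd.DataFrame({"t": self.t, "value": self.value}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ResponseCurve":
        df = pd.read_csv(path)
        return cls(t=df["t"].to_numpy(), value=df["value"].to_numpy())
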