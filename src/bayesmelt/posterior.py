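"""Container for joint posterior draws of the hierarchical model.

Draws are stored in natural space, one named column per parameter.  All
derived quantities — in particular per-protein melting temperatures
Tm_p = a_p / b_p — are computed per joint draw, never from posterior
means (Jensen: mean(a/b) != mean(a)/mean(b) in general).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PosteriorDraws"]


def _as_key(protein, proteins) -> tuple:
    """Normalize a protein reference to a (run_name, protein_id) tuple."""
    if isinstance(protein, tuple) and len(protein) == 2:
        key = protein
    else:
        matches = [k for k in proteins if k[1] == protein]
        if len(matches) > 1:
            raise KeyError(
                f"protein_id {protein!r} appears in several runs; pass (run_name, protein_id)"
            )
        key = matches[0] if matches else (None, protein)
    if key not in proteins:
        raise KeyError(f"unknown protein {protein!r}")
    return key


@dataclass
class PosteriorDraws:
    """Joint posterior draws with a name-to-column index.

    Attributes
    ----------
    draws : DataFrame
        n_draws × parameters, natural space. Column names follow
        ``a_r[run]``, ``delta_a[run/protein]`` etc.
    runs : list of str
    proteins : list of (run_name, protein_id)
    meta : dict
        Fit provenance: method, seed, steps/warmup, diagnostics, and for
        ADVI the objective trace.
    """

    draws: pd.DataFrame
    runs: list
    proteins: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.proteins = [tuple(k) for k in self.proteins]

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    # ------------------------------------------------------------- accessors

    def a_draws(self, protein) -> np.ndarray:
        run, pid = _as_key(protein, self.proteins)
        return (
            self.draws[f"a_r[{run}]"].to_numpy()
            + self.draws[f"delta_a[{run}/{pid}]"].to_numpy()
        )

    def b_draws(self, protein) -> np.ndarray:
        run, pid = _as_key(protein, self.proteins)
        return (
            self.draws[f"b_r[{run}]"].to_numpy()
            + self.draws[f"delta_b[{run}/{pid}]"].to_numpy()
        )

    def plateau_draws(self, protein) -> np.ndarray:
        run, pid = _as_key(protein, self.proteins)
        return self.draws[f"L_p[{run}/{pid}]"].to_numpy()

    def sigma_draws(self, protein) -> np.ndarray:
        run, pid = _as_key(protein, self.proteins)
        return self.draws[f"sigma_p[{run}/{pid}]"].to_numpy()

    def tm_draws(self, protein) -> np.ndarray:
        """Per-draw melting temperature a_p / b_p for one protein."""
        return self.a_draws(protein) / self.b_draws(protein)

    def run_tm_draws(self, run) -> np.ndarray:
        """Per-draw run-level melting temperature a_r / b_r."""
        return self.draws[f"a_r[{run}]"].to_numpy() / self.draws[f"b_r[{run}]"].to_numpy()

    # ------------------------------------------------------------- summaries

    def tm_summary(self, ci: float = 0.94) -> pd.DataFrame:
        """Per-protein Tm posterior mean, sd and equal-tailed interval."""
        lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
        rows = []
        for run, pid in self.proteins:
            t = self.tm_draws((run, pid))
            rows.append(
                {
                    "run_name": run,
                    "protein_id": pid,
                    "tm_mean": float(np.mean(t)),
                    "tm_sd": float(np.std(t, ddof=1)) if t.size > 1 else 0.0,
                    "tm_lo": float(np.quantile(t, lo_q)),
                    "tm_hi": float(np.quantile(t, hi_q)),
                }
            )
        return pd.DataFrame(rows)

    # ------------------------------------------------------------ persistence

    def save(self, path) -> tuple[Path, Path]:
        """Write draws as CSV plus a JSON sidecar with the index and meta."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        csv_path = path.with_suffix(".csv")
        json_path = path.with_suffix(".json")
        out = self.draws.copy()
        out.insert(0, "draw", np.arange(len(out)))
        out.to_csv(csv_path, index=False)
        meta = dict(self.meta)
        if isinstance(meta.get("elbo_trace"), np.ndarray):
            meta["elbo_trace"] = meta["elbo_trace"].tolist()
        sidecar = {
            "columns": list(self.draws.columns),
            "runs": list(self.runs),
            "proteins": [list(k) for k in self.proteins],
            "meta": meta,
        }
        json_path.write_text(json.dumps(sidecar, indent=1, default=str))
        return csv_path, json_path

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        draws = (
            pd.read_csv(path.with_suffix(".csv"), float_precision="round_trip")
            .drop(columns=["draw"])
            .astype(float)
        )
        return cls(
            draws=draws[sidecar["columns"]],
            runs=sidecar["runs"],
            proteins=[tuple(k) for k in sidecar["proteins"]],
            meta=sidecar.get("meta", {}),
        )

    @classmethod
    def from_arrays(cls, tm_arrays: dict, run: str = "run00") -> "PosteriorDraws":
        """Build a minimal posterior from per-protein Tm draw vectors.

        Convenience for decision analysis on hand-built draws: each vector
        becomes a_p (with b_p = 1), so ``tm_draws`` returns it unchanged.
        """
        n = {len(v) for v in tm_arrays.values()}
        if len(n) != 1:
            raise ValueError("all draw vectors must have equal length")
        cols = {f"a_r[{run}]": np.zeros(n.pop())}
        cols[f"b_r[{run}]"] = np.ones_like(cols[f"a_r[{run}]"])
        proteins = []
        for pid in sorted(tm_arrays):
            cols[f"delta_a[{run}/{pid}]"] = np.asarray(tm_arrays[pid], dtype=float)
            cols[f"delta_b[{run}/{pid}]"] = np.zeros_like(cols[f"delta_a[{run}/{pid}]"])
            proteins.append((run, pid))
        return cls(draws=pd.DataFrame(cols), runs=[run], proteins=proteins, meta={"source": "arrays"})
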