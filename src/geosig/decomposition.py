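"""Decomposition of de novo signatures into a reference catalogue.

Each de novo consensus signature is expressed as a nonnegative combination
of reference signatures (COSMIC-style catalogue) found by greedy forward
selection on reconstruction cosine, backward pruning, and a final
nonnegative least-squares refit; signatures whose best reconstruction stays
below a novelty threshold are flagged as novel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .schemas import ChannelSchema, get_schema


class SignatureMatrix:
    """Channels x signatures column-stochastic profile matrix."""

    def __init__(
        self,
        schema: ChannelSchema | str,
        names: list[str],
        profiles: np.ndarray,
        atol: float = 1e-8,
    ) -> None:
        if isinstance(schema, str):
            schema = get_schema(schema)
        profiles = np.asarray(profiles, dtype=float)
        if profiles.shape != (len(schema), len(names)):
            raise ValueError(
                f"profiles shape {profiles.shape} != ({len(schema)}, {len(names)})"
            )
        if (profiles < -atol).any():
            raise ValueError("profiles must be nonnegative")
        sums = profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("profile columns must sum to 1")
        self.schema = schema
        self.names = list(names)
        self.profiles = np.clip(profiles, 0.0, None)

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def profile(self, name: str) -> np.ndarray:
        return self.profiles[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles, index=list(self.schema.channels), columns=self.names
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, schema: ChannelSchema | str
    ) -> "SignatureMatrix":
        if isinstance(schema, str):
            schema = get_schema(schema)
        df = df.reindex(list(schema.channels))
        if df.isna().any().any():
            raise ValueError("frame is missing channels of the schema")
        return cls(schema, list(df.columns), df.to_numpy())

    def select(self, names: list[str]) -> "SignatureMatrix":
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(self.schema, names, self.profiles[:, idx])


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two nonnegative profiles; 1 iff proportional."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


@dataclass
class Decomposition:
    """Result of expressing one de novo signature over a reference set."""

    de_novo_id: str
    weights: dict[str, float]
    cosine: float
    residual_norm: float
    status: str  # "decomposed" | "novel"
    trace: list[tuple[str, str, float]] = field(default_factory=list, repr=False)

    def reconstruction(self, refs: SignatureMatrix) -> np.ndarray:
        v = np.zeros(len(refs.schema))
        for name, w in self.weights.items():
            v += w * refs.profile(name)
        return v

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "de_novo_id": self.de_novo_id,
                "reference_id": name,
                "weight": w,
                "cosine": self.cosine,
                "status": self.status,
            }
            for name, w in sorted(self.weights.items(), key=lambda kv: -kv[1])
        ]
        return pd.DataFrame(rows)


def _nnls_cosine(target: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, float]:
    w, _ = nnls(cols, target)
    recon = cols @ w
    if not recon.any():
        return w, 0.0
    return w, cosine_similarity(recon, target)


def decompose(
    de_novo: np.ndarray | pd.Series,
    refs: SignatureMatrix,
    de_novo_id: str = "de_novo",
    add_thresh: float = 0.01,
    remove_thresh: float = 0.01,
    novelty_cosine: float = 0.8,
) -> Decomposition:
    """Greedy sparse decomposition of a profile over reference signatures.

    Forward phase adds, one at a time, the reference that most improves
    reconstruction cosine while the gain exceeds ``add_thresh``; backward
    phase drops any retained reference whose removal costs less than
    ``remove_thresh``; weights are then refit by NNLS on the retained set.
    Final cosine below ``novelty_cosine`` marks the signature as novel.
    """
    target = np.asarray(de_novo, dtype=float)
    if target.shape[0] != len(refs.schema):
        raise ValueError("de novo profile and reference schema differ in length")
    if refs.n_signatures == 0:
        raise ValueError("reference set is empty")

    retained: list[int] = []
    current_cos = 0.0
    trace: list[tuple[str, str, float]] = []
    while len(retained) < refs.n_signatures:
        best_gain, best_j, best_cos = 0.0, None, current_cos
        for j in range(refs.n_signatures):
            if j in retained:
                continue
            cols = refs.profiles[:, retained + [j]]
            _, cos = _nnls_cosine(target, cols)
            if cos - current_cos > best_gain:
                best_gain, best_j, best_cos = cos - current_cos, j, cos
        if best_j is None or best_gain <= add_thresh:
            break
        retained.append(best_j)
        current_cos = best_cos
        trace.append(("add", refs.names[best_j], current_cos))

    # backward pruning: drop whichever reference costs least, while cheap
    while len(retained) > 1:
        best_drop, best_cost, best_cos = None, np.inf, current_cos
        for j in retained:
            rest = [i for i in retained if i != j]
            _, cos = _nnls_cosine(target, refs.profiles[:, rest])
            if current_cos - cos < best_cost:
                best_drop, best_cost, best_cos = j, current_cos - cos, cos
        if best_drop is None or best_cost >= remove_thresh:
            break
        retained.remove(best_drop)
        current_cos = best_cos
        trace.append(("remove", refs.names[best_drop], current_cos))

    if retained:
        w, cos = _nnls_cosine(target, refs.profiles[:, retained])
        recon = refs.profiles[:, retained] @ w
        weights = {
            refs.names[j]: float(wj) for j, wj in zip(retained, w) if wj > 0
        }
    else:
        weights, cos, recon = {}, 0.0, np.zeros_like(target)

    status = "decomposed" if cos >= novelty_cosine else "novel"
    return Decomposition(
        de_novo_id=de_novo_id,
        weights=weights,
        cosine=float(cos),
        residual_norm=float(np.linalg.norm(target - recon)),
        status=status,
        trace=trace,
    )


def decompose_all(
    de_novo: SignatureMatrix, refs: SignatureMatrix, **kwargs
) -> pd.DataFrame:
    """Decompose every de novo signature; returns the tidy long-form table."""
    frames = []
    for name in de_novo.names:
        d = decompose(de_novo.profile(name), refs, de_novo_id=name, **kwargs)
        if d.weights:
            frames.append(d.to_frame())
        else:
            frames.append(
                pd.DataFrame(
                    [
                        {
                            "de_novo_id": name,
                            "reference_id": None,
                            "weight": 0.0,
                            "cosine": d.cosine,
                            "status": d.status,
                        }
                    ]
                )
            )
    return pd.concat(frames, ignore_index=True)
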