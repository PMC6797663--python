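"""Serialization of fitted embeddings and posterior samples.

A fitted embedding is stored as a single zip archive containing a
coordinate table (``coordinates.csv``) and a kernel/attention-weight config
(``config.json``).  Floats are written with 17 significant digits so that
round-trips and determinism checks are exact.  Posterior samples go to a
``.npz`` array container with the chain settings embedded as a JSON sidecar
entry.
"""

from __future__ import annotations

import io as _io
import json
import zipfile

import numpy as np
import pandas as pd

from .kernel import KernelParams
from .likelihood import PsychEmbedding
from .posterior import PosteriorSamples

FLOAT_FMT = "%.17g"


def save_embedding(emb: PsychEmbedding, path) -> None:
    """Write an embedding archive (coordinates.csv + config.json)."""
    coords = pd.DataFrame(
        emb.z, columns=[f"dim{j}" for j in range(emb.n_dim)]
    )
    coords.insert(0, "stimulus", np.arange(emb.n_stimulus))
    config = {
        "kernel": emb.kernel.to_dict(),
        "weights": [[float(FLOAT_FMT % v) for v in row] for row in emb.weights],
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr(
            "coordinates.csv", coords.to_csv(index=False, float_format=FLOAT_FMT)
        )
        zf.writestr("config.json", json.dumps(config, indent=2))


def load_embedding(path) -> PsychEmbedding:
    with zipfile.ZipFile(path) as zf:
        coords = pd.read_csv(_io.BytesIO(zf.read("coordinates.csv")))
        config = json.loads(zf.read("config.json"))
    z = coords[[c for c in coords.columns if c.startswith("dim")]].to_numpy()
    kernel = KernelParams.from_dict(config["kernel"])
    weights = np.asarray(config["weights"], dtype=float)
    return PsychEmbedding(z, kernel, weights)


def save_samples(samples: PosteriorSamples, path) -> None:
    meta = json.dumps(
        {
            "shape": list(samples.samples.shape),
            "burn_in": samples.burn_in,
            "thin": samples.thin,
            "seed": samples.seed,
        }
    )
    np.savez(path, samples=samples.samples, meta=np.array(meta))


def load_samples(path) -> PosteriorSamples:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        return PosteriorSamples(
            data["samples"], burn_in=meta["burn_in"], thin=meta["thin"],
            seed=meta["seed"],
        )
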