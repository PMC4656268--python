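"""Model serialization.

A trained model is a single versioned JSON file holding the dual solution
(support vectors, alpha*y coefficients, bias), the kernel and penalty
settings, and — crucially — the full feature-extraction configuration
(wavelet, level, q, estimator, optional scaler).  Prediction reads the
extraction settings from the file, never from user flags, so the online
phase cannot drift from the offline training configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError
from .fsvm import FSVMModel, KernelSpec

FORMAT_VERSION = 1


def model_to_dict(model: FSVMModel, extraction: dict | None = None) -> dict:
    mask = model.alpha > 1e-12
    return {
        "format_version": FORMAT_VERSION,
        "extraction": extraction or model.extraction or {},
        "model": {
            "kernel": {
                "name": model.kernel.name,
                "gamma": model.gamma,
                "degree": model.kernel.degree,
                "coef0": model.kernel.coef0,
            },
            "C": model.C,
            "delta": model.delta,
            "b": model.b,
            "alpha": model.alpha[mask].tolist(),
            "support_vectors": model.X[mask].tolist(),
            "labels": model.y[mask].tolist(),
            "memberships": model.memberships[mask].tolist(),
        },
    }


def dict_to_model(payload: dict) -> FSVMModel:
    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise ConfigurationError(
            f"model file format version {version!r} not supported "
            f"(expected {FORMAT_VERSION})"
        )
    m = payload["model"]
    kernel = KernelSpec(name=m["kernel"]["name"], gamma=m["kernel"]["gamma"],
                        degree=m["kernel"]["degree"], coef0=m["kernel"]["coef0"])
    model = FSVMModel(
        X=np.asarray(m["support_vectors"], dtype=float),
        y=np.asarray(m["labels"], dtype=float),
        alpha=np.asarray(m["alpha"], dtype=float),
        b=float(m["b"]),
        C=float(m["C"]),
        kernel=kernel,
        gamma=float(m["kernel"]["gamma"]),
        memberships=np.asarray(m["memberships"], dtype=float),
        delta=m.get("delta"),
        extraction=payload.get("extraction") or {},
    )
    return model


def save_model(model: FSVMModel, path, extraction: dict | None = None) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model, extraction), indent=2))


def load_model(path) -> FSVMModel:
    return dict_to_model(json.loads(Path(path).read_text()))
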