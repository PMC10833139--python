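"""Versioned model serialization with bit-exact numeric round-trips.

Models are written as a single self-describing JSON document: a manifest
(format tag, version, class name) plus a payload in which every numpy array
is stored as base64-encoded raw bytes with dtype and shape, so reloading
reproduces each numeric field bit-identically.
"""

from __future__ import annotations

import base64
import dataclasses
import json

import numpy as np
import pandas as pd

from .exceptions import ModelIOError

FORMAT_TAG = "mvintegrate-model"
FORMAT_VERSION = 1

_MODEL_REGISTRY: dict[str, type] = {}


def register_model(cls):
    """Class decorator: make a dataclass save/load-able by name."""
    _MODEL_REGISTRY[cls.__name__] = cls
    return cls


def _encode(obj):
    if obj is None or isinstance(obj, (bool, int, str)):
        return obj
    if isinstance(obj, float):
        return {"__float__": obj.hex()}
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return _encode(obj.item())
    if isinstance(obj, np.ndarray):
        arr = np.ascontiguousarray(obj)
        return {
            "__ndarray__": base64.b64encode(arr.tobytes()).decode("ascii"),
            "dtype": arr.dtype.str,
            "shape": list(arr.shape),
        }
    if isinstance(obj, pd.DataFrame):
        return {
            "__dataframe__": {c: _encode(obj[c].to_numpy()) for c in obj.columns},
            "columns": list(map(str, obj.columns)),
        }
    if isinstance(obj, (list, tuple)):
        return {"__list__": [_encode(x) for x in obj], "tuple": isinstance(obj, tuple)}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        name = type(obj).__name__
        if name not in _MODEL_REGISTRY:
            raise ModelIOError(f"{name} is not registered for serialization")
        payload = {f.name: _encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        return {"__model__": name, "payload": payload}
    if isinstance(obj, dict):
        return {"__dict__": {str(k): _encode(v) for k, v in obj.items()}}
    raise ModelIOError(f"cannot serialize object of type {type(obj).__name__}")


def _decode(obj):
    if obj is None or isinstance(obj, (bool, int, str)):
        return obj
    if isinstance(obj, float):  # legacy / integral-valued floats
        return obj
    if isinstance(obj, dict):
        if "__float__" in obj:
            return float.fromhex(obj["__float__"])
        if "__ndarray__" in obj:
            raw = base64.b64decode(obj["__ndarray__"])
            return np.frombuffer(raw, dtype=np.dtype(obj["dtype"])).reshape(obj["shape"]).copy()
        if "__dataframe__" in obj:
            data = {c: _decode(v) for c, v in obj["__dataframe__"].items()}
            return pd.DataFrame(data, columns=obj["columns"])
        if "__list__" in obj:
            seq = [_decode(x) for x in obj["__list__"]]
            return tuple(seq) if obj.get("tuple") else seq
        if "__model__" in obj:
            cls = _MODEL_REGISTRY.get(obj["__model__"])
            if cls is None:
                raise ModelIOError(f"unknown model class {obj['__model__']!r}")
            kwargs = {k: _decode(v) for k, v in obj["payload"].items()}
            return _construct(cls, kwargs)
        if "__dict__" in obj:
            return {k: _decode(v) for k, v in obj["__dict__"].items()}
    raise ModelIOError(f"cannot deserialize fragment: {obj!r}")


def _construct(cls, kwargs):
    obj = object.__new__(cls)
    for k, v in kwargs.items():
        object.__setattr__(obj, k, v)
    return obj


def save_model(model, path) -> None:
    """Serialize a fitted, registered model dataclass to ``path`` (JSON)."""
    doc = {
        "format": FORMAT_TAG,
        "version": FORMAT_VERSION,
        "class": type(model).__name__,
        "body": _encode(model),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path):
    """Inverse of :func:`save_model`; raises :class:`ModelIOError` on damage."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, OSError, UnicodeDecodeError) as exc:
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != FORMAT_TAG:
        raise ModelIOError(f"{path} is not a {FORMAT_TAG} file")
    if doc.get("version") != FORMAT_VERSION:
        raise ModelIOError(
            f"model format version {doc.get('version')} unsupported "
            f"(expected {FORMAT_VERSION})"
        )
    return _decode(doc["body"])
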