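"""Glue between ensemble recipes and descriptor computation: expand an
:class:`~protdesc.ensemble.EnsembleSpec` into per-component feature tables
for a dataset bundle, so the evaluation protocols can train one SVM per
component."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import matrix_descriptors as md
from . import seq_descriptors as sd
from . import texture
from .core import (PhysicochemicalProperty, ProfileMatrix, ProteinRecord,
                   SubstitutionMatrix)
from .ensemble import EnsembleSpec
from .representations import build_dm, build_smr


@dataclass
class DatasetBundle:
    """Everything an ensemble may consume for one dataset: sequences and,
    as available, their profile matrices, backbone coordinates, the
    physicochemical property list and a substitution matrix."""

    records: list[ProteinRecord]
    profiles: list[ProfileMatrix] | None = None
    backbones: list[np.ndarray] | None = None
    properties: list[PhysicochemicalProperty] | None = None
    substitution_matrix: SubstitutionMatrix | None = None


def _matrix_descriptor_row(mat: ProfileMatrix, record: ProteinRecord,
                           descriptor: str) -> np.ndarray:
    if descriptor == "SA":
        return np.asarray(md.single_average(mat, record))
    if descriptor == "SAN":
        return np.asarray(md.single_average(mat, record, normalize=True))
    if descriptor == "AB":
        return np.asarray(md.average_blocks(mat))
    if descriptor == "AM":
        return np.asarray(md.autocovariance_matrix(mat))
    if descriptor == "PP":
        return np.asarray(md.pseudo_pssm(mat))
    if descriptor == "BGR":
        return np.asarray(md.ngram_matrix(mat)[0])
    if descriptor == "TGR":
        return np.asarray(md.ngram_matrix(mat)[1])
    if descriptor == "DCT":
        return np.asarray(md.dct_descriptor(mat.values))
    if descriptor == "SVD":
        return np.asarray(md.svd_descriptor(mat.values, pad_to=20))
    if descriptor == "LHF_G":
        return np.asarray(texture.lbp_hf(mat))
    if descriptor == "LPQ_G":
        return np.asarray(texture.lpq(mat))
    if descriptor == "LHF_L":
        return np.asarray(texture.local3(mat, texture.lbp_hf))
    if descriptor == "LPQ_L":
        return np.asarray(texture.local3(mat, texture.lpq))
    raise ValueError(f"unknown matrix descriptor {descriptor!r}")


def expand_ensemble(spec: EnsembleSpec, bundle: DatasetBundle,
                    seed: int = 0):
    """Expand an ensemble spec into (feature_tables, weights).

    Property-parameterized components (the AAS(AC) sub-ensemble) emit one
    table per property with the component weight split evenly, so the
    unit-weight property fusion nests inside the outer weighted sum.
    """
    tables: list[np.ndarray] = []
    weights: list[float] = []
    records = bundle.records
    smr_cache: list[ProfileMatrix] | None = None
    dm_cache: list | None = None

    for representation, descriptor, weight in spec.components:
        if representation == "AAS":
            if descriptor == "AC":
                props = bundle.properties
                if not props:
                    raise ValueError("AAS(AC) needs a property list")
                for d in props:
                    tables.append(np.vstack(
                        [np.asarray(sd.autocovariance(r, d))
                         for r in records]))
                    weights.append(weight / len(props))
            elif descriptor.startswith("NG_"):
                alphabet = descriptor.split("_", 1)[1]
                tables.append(np.vstack(
                    [np.asarray(sd.ngram(r, alphabet)) for r in records]))
                weights.append(weight)
            elif descriptor == "AAC":
                tables.append(np.vstack(
                    [np.asarray(sd.aac(r)) for r in records]))
                weights.append(weight)
            else:
                raise ValueError(
                    f"unsupported sequence component {descriptor!r}")
            continue

        if representation == "PSSM":
            if bundle.profiles is None:
                raise ValueError("PSSM components need profile matrices")
            mats = bundle.profiles
        elif representation == "SMR":
            if bundle.substitution_matrix is None:
                raise ValueError("SMR components need a substitution matrix")
            if smr_cache is None:
                smr_cache = [build_smr(r, bundle.substitution_matrix)
                             for r in records]
            mats = smr_cache
        elif representation == "DM":
            if bundle.backbones is None:
                raise ValueError("DM components need backbone coordinates")
            if dm_cache is None:
                dm_cache = [build_dm(c) for c in bundle.backbones]
            mats = dm_cache
        else:
            raise ValueError(f"unknown representation {representation!r}")

        tables.append(np.vstack(
            [_matrix_descriptor_row(m, r, descriptor)
             for m, r in zip(mats, records)]))
        weights.append(weight)

    return tables, np.array(weights)
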