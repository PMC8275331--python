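"""Readers, writers and dataset-split logic for every external representation.

Text formats only: GCT 1.2/1.3 for signature matrices (column metadata in a
``<name>.meta.tsv`` sidecar for 1.2), GMT for pathway gene sets, and simple TSV
dialects for SMILES lists, fingerprints, MoA truth labels and score tables.
Numeric round-trips are exact at 10 significant digits (the writer precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    FingerprintBackendError,
    FormatError,
    GctParseError,
    SmilesError,
    ValidationError,
)

GP_PERT_TYPES = ("knock-down", "knock-out", "over-expression")
PERT_TYPES = ("compound",) + GP_PERT_TYPES

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CompoundRecord:
    """One compound: id plus structure as SMILES and/or a binary fingerprint.

    At least one of ``smiles``/``fingerprint`` must be present. ``signature_ids``
    lists the sample columns (in a :class:`SignatureMatrix`) induced by this
    compound; it may be empty for structure-only compounds.
    """

    compound_id: str
    smiles: str | None = None
    fingerprint: np.ndarray | None = None
    signature_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.smiles is None and self.fingerprint is None:
            raise ValidationError(
                f"compound {self.compound_id!r}: need smiles or fingerprint"
            )
        if self.fingerprint is not None:
            fp = np.asarray(self.fingerprint)
            if fp.ndim != 1:
                raise ValidationError(
                    f"compound {self.compound_id!r}: fingerprint must be 1-D"
                )
            if not np.isin(fp, (0, 1)).all():
                raise ValidationError(
                    f"compound {self.compound_id!r}: fingerprint entries must be 0/1"
                )
            self.fingerprint = fp.astype(np.uint8)


@dataclass
class SignatureMatrix:
    """Genes x samples signature matrix with per-sample metadata.

    ``column_meta`` maps sample_id -> dict with keys ``perturbagen_id``,
    ``pert_type`` (one of ``compound``, ``knock-down``, ``knock-out``,
    ``over-expression``), ``target_gene`` (required and non-empty for genetic
    perturbation columns) and optional ``cell_line``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    column_meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self):
        G, S = len(self.gene_ids), len(self.sample_ids)
        if self.values.shape != (G, S):
            raise ValidationError(
                f"values shape {self.values.shape} != (genes={G}, samples={S})"
            )
        if len(set(self.sample_ids)) != S:
            raise ValidationError("duplicate sample_ids")
        if not np.isfinite(self.values).all():
            raise ValidationError("signature values must be finite")
        for sid, meta in self.column_meta.items():
            pt = meta.get("pert_type")
            if pt is not None and pt not in PERT_TYPES:
                raise ValidationError(f"sample {sid!r}: unknown pert_type {pt!r}")
            if pt in GP_PERT_TYPES and not meta.get("target_gene"):
                raise ValidationError(
                    f"sample {sid!r}: genetic-perturbation column lacks target_gene"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def gp_columns(self) -> list[str]:
        return [
            s
            for s in self.sample_ids
            if self.column_meta.get(s, {}).get("pert_type") in GP_PERT_TYPES
        ]


@dataclass
class PathwayCollection:
    """pathway_id -> set of gene symbols."""

    pathways: dict[str, set[str]]
    source_name: str = ""

    def __post_init__(self):
        for pid, genes in self.pathways.items():
            if not genes:
                raise ValidationError(f"pathway {pid!r} has an empty gene set")
            if any(not g for g in genes):
                raise ValidationError(f"pathway {pid!r} contains an empty gene symbol")

    def __len__(self):
        return len(self.pathways)

    def __getitem__(self, pid: str) -> set[str]:
        return self.pathways[pid]

    def items(self):
        return self.pathways.items()

    def uppercased(self) -> "PathwayCollection":
        """Uppercase-normalized copy, for symbol harmonization across sources."""
        return PathwayCollection(
            {p: {g.upper() for g in gs} for p, gs in self.pathways.items()},
            self.source_name,
        )


@dataclass
class SplitSpec:
    """Train/validation/test fractions plus the shuffling seed."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self):
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValidationError("fractions must be three positive numbers")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValidationError("fractions must sum to 1")


# ---------------------------------------------------------------------------
# GCT
# ---------------------------------------------------------------------------

def _meta_sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.tsv")


def read_signature_gct(path, meta_path=None) -> SignatureMatrix:
    """Read a GCT 1.2 or 1.3 text file into a :class:`SignatureMatrix`.

    For GCT 1.2, per-sample metadata is read from ``<file>.meta.tsv`` when
    present (columns: sample_id, perturbagen_id, pert_type, target_gene,
    cell_line). GCT 1.3 column-metadata rows named after those keys are parsed
    from the file itself.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    version = lines[0].strip()
    if version not in ("#1.2", "#1.3"):
        raise FormatError(f"{path}: unsupported GCT version line {version!r}")
    dims = lines[1].split("\t")
    try:
        dims = [int(x) for x in dims]
    except ValueError:
        raise FormatError(f"{path}: malformed dimension line: {lines[1]!r}")
    if version == "#1.2":
        if len(dims) != 2:
            raise FormatError(f"{path}: malformed dimension line: {lines[1]!r}")
        n_rows, n_cols = dims
        n_rmeta, n_cmeta = 1, 0  # the Description column only
    else:
        if len(dims) != 4:
            raise FormatError(f"{path}: malformed dimension line: {lines[1]!r}")
        n_rows, n_cols, n_rmeta, n_cmeta = dims

    header = lines[2].split("\t")
    expected_header_len = 1 + n_rmeta + n_cols
    if len(header) != expected_header_len:
        raise FormatError(
            f"{path}: header has {len(header)} fields, expected {expected_header_len}"
        )
    sample_ids = header[1 + n_rmeta:]

    body = lines[3:]
    col_meta_rows = body[:n_cmeta]
    data_rows = body[n_cmeta:]
    data_rows = [r for r in data_rows if r.strip()]
    if len(data_rows) != n_rows:
        raise FormatError(
            f"{path}: declared {n_rows} data rows but found {len(data_rows)}"
        )

    column_meta: dict[str, dict] = {s: {} for s in sample_ids}
    for row in col_meta_rows:
        fields = row.split("\t")
        key = fields[0]
        vals = fields[1 + n_rmeta:]
        for sid, v in zip(sample_ids, vals):
            if v not in ("", "NA", "-666"):
                column_meta[sid][key] = v

    gene_ids: list[str] = []
    values = np.empty((n_rows, n_cols))
    for i, row in enumerate(data_rows):
        fields = row.split("\t")
        if len(fields) != expected_header_len:
            raise FormatError(
                f"{path}: data row {i} has {len(fields)} fields, "
                f"expected {expected_header_len}"
            )
        gene_ids.append(fields[0])
        for j, cell in enumerate(fields[1 + n_rmeta:]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise GctParseError(
                    f"{path}: non-numeric cell {cell!r}", row=i, col=j
                )

    if meta_path is None:
        candidate = _meta_sidecar_path(path)
        meta_path = candidate if candidate.exists() else None
    if meta_path is not None:
        side = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
        if "sample_id" not in side.columns:
            raise FormatError(f"{meta_path}: sidecar needs a sample_id column")
        for _, r in side.iterrows():
            sid = r["sample_id"]
            if sid in column_meta:
                column_meta[sid].update(
                    {k: v for k, v in r.items() if k != "sample_id" and v != ""}
                )
    return SignatureMatrix(gene_ids, sample_ids, values, column_meta)


def write_signature_gct(sm: SignatureMatrix, path, meta_path=None) -> None:
    """Write GCT 1.2 plus a ``<file>.meta.tsv`` sidecar when metadata exists."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{sm.n_genes}\t{sm.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(sm.sample_ids) + "\n")
        for i, g in enumerate(sm.gene_ids):
            row = "\t".join(FLOAT_FMT % v for v in sm.values[i])
            fh.write(f"{g}\t{g}\t{row}\n")
    if sm.column_meta and any(sm.column_meta.values()):
        if meta_path is None:
            meta_path = _meta_sidecar_path(path)
        keys = ["perturbagen_id", "pert_type", "target_gene", "cell_line"]
        with open(meta_path, "w") as fh:
            fh.write("sample_id\t" + "\t".join(keys) + "\n")
            for sid in sm.sample_ids:
                meta = sm.column_meta.get(sid, {})
                fh.write(sid + "\t" + "\t".join(meta.get(k, "") for k in keys) + "\n")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path, source_name: str | None = None) -> PathwayCollection:
    """Read a GMT file: ``pathway_id<TAB>description<TAB>gene...`` per line."""
    path = Path(path)
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            pid = fields[0]
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway {pid!r} has no genes")
            pathways[pid] = genes
    return PathwayCollection(pathways, source_name or path.name)


def write_gmt(pc: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(pc.pathways):
            genes = sorted(pc.pathways[pid])
            fh.write(pid + "\t" + (pc.source_name or pid) + "\t" + "\t".join(genes) + "\n")


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

def read_smiles_tsv(path) -> dict[str, str]:
    """``compound_id<TAB>smiles`` per line (no header)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            out[fields[0]] = fields[1]
    return out


def read_fingerprint_tsv(path) -> dict[str, np.ndarray]:
    """``compound_id<TAB>0/1-string`` per line (no header)."""
    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or set(fields[1]) - {"0", "1"}:
                raise FormatError(
                    f"{path}:{lineno}: expected 'id<TAB><0/1 string>'"
                )
            out[fields[0]] = np.frombuffer(
                fields[1].encode(), dtype=np.uint8
            ) - ord("0")
    return out


def write_fingerprint_tsv(fps: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for cid, fp in fps.items():
            fh.write(cid + "\t" + "".join("1" if b else "0" for b in fp) + "\n")


def read_truth_tsv(path) -> dict[str, set[str]]:
    """``compound_id<TAB>pathway_id`` per line; multiple rows per compound."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            out.setdefault(fields[0], set()).add(fields[1])
    return out


def write_truth_tsv(truth: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(truth):
            for pid in sorted(truth[cid]):
                fh.write(f"{cid}\t{pid}\n")


# ---------------------------------------------------------------------------
# compound-disjoint split
# ---------------------------------------------------------------------------

def _largest_remainder_sizes(n: int, fractions) -> list[int]:
    # floor every share, hand out leftovers by fractional part, earlier split
    # wins ties -- so (0.7, 0.15, 0.15) on n=10 yields (7, 2, 1)
    raw = [n * f for f in fractions]
    sizes = [math.floor(r) for r in raw]
    leftovers = n - sum(sizes)
    order = sorted(range(len(fractions)), key=lambda i: (-(raw[i] - sizes[i]), i))
    for i in order[:leftovers]:
        sizes[i] += 1
    return sizes


def split_compounds(
    records: list[CompoundRecord], spec: SplitSpec
) -> tuple[list[CompoundRecord], list[CompoundRecord], list[CompoundRecord]]:
    """Partition compounds (and with them all their signatures) into
    train/validation/test with no compound shared across splits.

    Sizes follow the fractions by the largest-remainder rule; the shuffle is a
    seeded permutation, so the partition is reproducible.
    """
    if len(records) < 3:
        raise ValidationError("need at least 3 compounds to form 3 splits")
    ids = [r.compound_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate compound_ids in corpus")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(records))
    sizes = _largest_remainder_sizes(len(records), spec.fractions)
    shuffled = [records[i] for i in perm]
    train = shuffled[: sizes[0]]
    val = shuffled[sizes[0]: sizes[0] + sizes[1]]
    test = shuffled[sizes[0] + sizes[1]:]
    return train, val, test


# ---------------------------------------------------------------------------
# fingerprints from SMILES
# ---------------------------------------------------------------------------

def smiles_to_fingerprint(smiles: str, n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    """Hash a SMILES into an ECFP-style binary Morgan fingerprint.

    Radius 2 gives the ECFP4 convention. Requires RDKit; everything downstream
    only consumes bit vectors, so precomputed fingerprints work when no
    cheminformatics backend is installed.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - rdkit present in CI image
        raise FingerprintBackendError(
            "RDKit is not installed; supply precomputed fingerprints instead"
        ) from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprintAsNumPy(mol)
    return fp.astype(np.uint8)
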