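"""Fixed-length numeric descriptor encodings of protein sequences.

Nine descriptor families are provided:

====================  ====  =======================================================
name                  dim   summary
====================  ====  =======================================================
``aac``                 20  amino acid composition (fractions)
``dipep``              400  overlapping dipeptide composition
``ct``                 343  conjoint-triad composition over 7 residue groups
``ctd``                 63  composition / transition / distribution over the groups
``moran``              240  Moran autocorrelation, 8 properties x lags 1..30
``geary``              240  Geary autocorrelation
``mba``                240  Moreau-Broto autocorrelation (length-normalized)
``physchem``            24  scaled physicochemical summary (class fractions, pI, MW)
``saac``                60  split amino acid composition (N-term / center / C-term)
``composite``           44  ``aac`` concatenated with ``physchem``
====================  ====  =======================================================

All composition-type features are fractions in [0, 1].  Autocorrelation
descriptors are computed on eight classical amino-acid property scales
(hydrophobicity, flexibility, polarizability, free energy of solution,
accessible surface area, volume, steric parameter, relative mutability),
each z-normalized over the 20 residues; alternative scales can be supplied
through :class:`PropertySet`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from seqsubtype.errors import LengthError, SeqSubtypeError
from seqsubtype.sequence_io import STANDARD_RESIDUES, ProteinRecord

_RESIDUE_INDEX = {aa: i for i, aa in enumerate(STANDARD_RESIDUES)}

#: 7 disjoint residue groups (dipole/volume classes) used by the conjoint
#: triad and CTD descriptors; together they cover the standard alphabet.
CONJOINT_GROUPS: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")
_GROUP_OF = {aa: g for g, members in enumerate(CONJOINT_GROUPS) for aa in members}

#: Average residue masses (Da); one water (18.0153 Da) is added per chain.
RESIDUE_MASS = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155, "F": 147.1766,
    "G": 57.0519, "H": 137.1411, "I": 113.1594, "K": 128.1741, "L": 113.1594,
    "M": 131.1926, "N": 114.1038, "P": 97.1167, "Q": 128.1307, "R": 156.1875,
    "S": 87.0782, "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
WATER_MASS = 18.0153

#: pKa values for the net-charge model behind the isoelectric point: chain
#: termini plus the ionizable side chains.
PKA = {
    "n_term": 9.69, "c_term": 2.34,
    "D": 3.65, "E": 4.25, "C": 8.3, "Y": 10.07, "H": 6.0, "K": 10.53, "R": 12.48,
}

# Residue classes of the 24-element physicochemical vector (order matters).
_PHYSCHEM_CLASSES = [
    ("charged", "DREKH"),
    ("hydrophilic_neutral", "NQSTY"),
    ("basic", "HKR"),
    ("acidic", "DE"),
    ("aliphatic", "AGILV"),
    ("aromatic", "FWY"),
    ("small", "DNT"),
    ("tiny", "AGPS"),
    ("large", "FRWY"),
    ("hydrophobic_aromatic", "WF"),
    ("hydrophobic_neutral", "ACGILMFPWV"),
    ("amidic", "NQ"),
    ("cyclic", "P"),
    ("hydroxylic", "ST"),
    ("sulfur", "CM"),
    ("h_bonding", "CWNQSTYKRHDE"),
    ("acidic_amide", "DENQ"),
    ("ionizable", "DEHCYKR"),
    ("sulfur_bonding", "C"),
]

PHYSCHEM_FEATURE_NAMES = (
    ["log_mw", "log_length"]
    + [name for name, _ in _PHYSCHEM_CLASSES]
    + ["pI", "mw_scaled", "length_scaled"]
)


@dataclass(frozen=True)
class FeatureMatrix:
    """Named descriptor vectors for a set of records (rows x features)."""

    descriptor_name: str
    row_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape != (len(self.row_ids), len(self.feature_names)):
            raise SeqSubtypeError(
                f"feature matrix shape {v.shape} does not match "
                f"{len(self.row_ids)} ids x {len(self.feature_names)} features"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_ids), columns=list(self.feature_names))

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, descriptor_name: str = "") -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            descriptor_name=descriptor_name,
            row_ids=tuple(str(i) for i in df.index),
            feature_names=tuple(df.columns),
            values=df.to_numpy(dtype=float),
        )


class PropertySet:
    """Eight (or user-supplied) amino-acid property scales.

    Each scale maps every one of the 20 standard residues to a real value.
    With ``normalize=True`` (the default) each scale is z-normalized over
    the 20 residues (mean 0, unit standard deviation) before use, the
    standard pre-processing for autocorrelation descriptors.
    """

    def __init__(self, scales: dict[str, dict[str, float]], normalize: bool = True):
        self.names = tuple(scales)
        self.normalized = normalize
        self._tables: dict[str, dict[str, float]] = {}
        for name, scale in scales.items():
            missing = set(STANDARD_RESIDUES) - set(scale)
            if missing:
                raise SeqSubtypeError(f"scale {name!r} missing residues {sorted(missing)}")
            vals = np.array([scale[aa] for aa in STANDARD_RESIDUES], dtype=float)
            if normalize:
                sd = vals.std()
                if sd == 0:
                    vals = np.zeros_like(vals)
                else:
                    vals = (vals - vals.mean()) / sd
            self._tables[name] = dict(zip(STANDARD_RESIDUES, vals))

    def profile(self, name: str, sequence: str) -> np.ndarray:
        """Per-position property values of ``sequence`` under scale ``name``."""
        table = self._tables[name]
        return np.array([table[aa] for aa in sequence], dtype=float)

    @classmethod
    def default(cls, normalize: bool = True) -> "PropertySet":
        """The packaged eight-scale table (see ``data/aa_properties.tsv``)."""
        with resources.files("seqsubtype").joinpath("data/aa_properties.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", index_col="residue")
        scales = {col: df[col].to_dict() for col in df.columns}
        return cls(scales, normalize=normalize)

    @classmethod
    def from_tsv(cls, path: str | Path, normalize: bool = True) -> "PropertySet":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls({col: df[col].to_dict() for col in df.columns}, normalize=normalize)


_DEFAULT_PROPS: PropertySet | None = None


def default_properties() -> PropertySet:
    global _DEFAULT_PROPS
    if _DEFAULT_PROPS is None:
        _DEFAULT_PROPS = PropertySet.default()
    return _DEFAULT_PROPS


# ---------------------------------------------------------------------------
# composition descriptors


def aac(record: ProteinRecord) -> np.ndarray:
    """20-element amino acid composition (fractions, fixed residue order)."""
    return _aac_str(record.sequence)


def _aac_str(seq: str) -> np.ndarray:
    counts = np.zeros(20)
    for aa in seq:
        counts[_RESIDUE_INDEX[aa]] += 1
    return counts / len(seq)


def dipep(record: ProteinRecord) -> np.ndarray:
    """400-element overlapping dipeptide composition."""
    seq = record.sequence
    if len(seq) < 2:
        raise LengthError(f"dipep requires length >= 2, got {len(seq)}")
    counts = np.zeros((20, 20))
    for a, b in zip(seq, seq[1:]):
        counts[_RESIDUE_INDEX[a], _RESIDUE_INDEX[b]] += 1
    return counts.ravel() / (len(seq) - 1)


def conjoint_triad(record: ProteinRecord) -> np.ndarray:
    """343-element triad composition over the 7 conjoint residue groups."""
    seq = record.sequence
    if len(seq) < 3:
        raise LengthError(f"conjoint_triad requires length >= 3, got {len(seq)}")
    g = [_GROUP_OF[aa] for aa in seq]
    counts = np.zeros((7, 7, 7))
    for i in range(len(g) - 2):
        counts[g[i], g[i + 1], g[i + 2]] += 1
    return counts.ravel() / (len(seq) - 2)


def ctd(record: ProteinRecord) -> np.ndarray:
    """63-element composition/transition/distribution descriptor.

    7 group compositions, 21 unordered-group-pair transition frequencies
    (adjacent positions, divided by length - 1), and for each group the
    sequence positions -- as percent of sequence length -- of its first,
    25%, 50%, 75% and 100% occurrence (0 for absent groups).
    """
    seq = record.sequence
    n = len(seq)
    if n < 2:
        raise LengthError(f"ctd requires length >= 2, got {n}")
    g = np.array([_GROUP_OF[aa] for aa in seq])

    comp = np.bincount(g, minlength=7) / n

    trans = np.zeros((7, 7))
    for a, b in zip(g, g[1:]):
        if a != b:
            lo, hi = min(a, b), max(a, b)
            trans[lo, hi] += 1
    trans_vec = np.array([trans[i, j] for i in range(7) for j in range(i + 1, 7)]) / (n - 1)

    dist = np.zeros((7, 5))
    for grp in range(7):
        pos = np.flatnonzero(g == grp) + 1  # 1-based positions
        if pos.size == 0:
            continue
        c = pos.size
        for qi, q in enumerate((0.0, 0.25, 0.50, 0.75, 1.0)):
            idx = 1 if q == 0.0 else int(np.ceil(q * c))
            dist[grp, qi] = pos[idx - 1] / n * 100.0
    return np.concatenate([comp, trans_vec, dist.ravel()])


# ---------------------------------------------------------------------------
# autocorrelation descriptors


def _check_autocorr_length(seq: str, max_lag: int) -> None:
    if len(seq) <= max_lag:
        raise LengthError(
            f"autocorrelation with max_lag={max_lag} requires length >= {max_lag + 1}, "
            f"got {len(seq)}"
        )


def moran(record: ProteinRecord, props: PropertySet | None = None, max_lag: int = 30) -> np.ndarray:
    """Moran autocorrelation over each property scale at lags 1..max_lag.

    At lag d the statistic is the lag-d autocovariance (averaged over the
    N - d pairs, deviations from the whole-sequence property mean) divided
    by the full-sequence variance (averaged over N).  Constant property
    profiles give 0 by convention.
    """
    props = props or default_properties()
    seq = record.sequence
    _check_autocorr_length(seq, max_lag)
    n = len(seq)
    out = np.empty(len(props.names) * max_lag)
    for pi, name in enumerate(props.names):
        p = props.profile(name, seq)
        dev = p - p.mean()
        denom = (dev * dev).sum() / n
        for d in range(1, max_lag + 1):
            if denom < 1e-300:
                val = 0.0
            else:
                val = (dev[: n - d] * dev[d:]).sum() / (n - d) / denom
            out[pi * max_lag + (d - 1)] = val
    return out


def geary(record: ProteinRecord, props: PropertySet | None = None, max_lag: int = 30) -> np.ndarray:
    """Geary autocorrelation: half the mean squared lag-d difference divided
    by the (N - 1)-denominator sample variance; 0 for constant profiles."""
    props = props or default_properties()
    seq = record.sequence
    _check_autocorr_length(seq, max_lag)
    n = len(seq)
    out = np.empty(len(props.names) * max_lag)
    for pi, name in enumerate(props.names):
        p = props.profile(name, seq)
        dev = p - p.mean()
        denom = (dev * dev).sum() / (n - 1)
        for d in range(1, max_lag + 1):
            if denom < 1e-300:
                val = 0.0
            else:
                diff = p[: n - d] - p[d:]
                val = (diff * diff).sum() / (2 * (n - d)) / denom
            out[pi * max_lag + (d - 1)] = val
    return out


def moreau_broto(
    record: ProteinRecord,
    props: PropertySet | None = None,
    max_lag: int = 30,
    normalize_by_length: bool = True,
) -> np.ndarray:
    """Moreau-Broto autocorrelation: sum of lag-d property products.

    By default the raw sum is divided by the number of terms (N - d) so
    values are comparable across sequence lengths; ``normalize_by_length=
    False`` restores the raw sum.
    """
    props = props or default_properties()
    seq = record.sequence
    _check_autocorr_length(seq, max_lag)
    n = len(seq)
    out = np.empty(len(props.names) * max_lag)
    for pi, name in enumerate(props.names):
        p = props.profile(name, seq)
        for d in range(1, max_lag + 1):
            val = (p[: n - d] * p[d:]).sum()
            if normalize_by_length:
                val /= n - d
            out[pi * max_lag + (d - 1)] = val
    return out


# ---------------------------------------------------------------------------
# physicochemical summary


def molecular_weight(record: ProteinRecord) -> float:
    """Average molecular weight in daltons (residue masses plus one water)."""
    return sum(RESIDUE_MASS[aa] for aa in record.sequence) + WATER_MASS


def _net_charge(sequence: str, ph: float) -> float:
    pos = 1.0 / (1.0 + 10 ** (ph - PKA["n_term"]))
    neg = 1.0 / (1.0 + 10 ** (PKA["c_term"] - ph))
    for aa, pka in (("K", PKA["K"]), ("R", PKA["R"]), ("H", PKA["H"])):
        pos += sequence.count(aa) / (1.0 + 10 ** (ph - pka))
    for aa, pka in (("D", PKA["D"]), ("E", PKA["E"]), ("C", PKA["C"]), ("Y", PKA["Y"])):
        neg += sequence.count(aa) / (1.0 + 10 ** (pka - ph))
    return pos - neg


def isoelectric_point(record: ProteinRecord, tol: float = 1e-4) -> float:
    """pH at which the Henderson-Hasselbalch net charge is zero (bisection).

    The charge model covers both termini and the D, E, C, Y, H, K, R side
    chains.  Net charge is monotonically decreasing in pH, so bisection on
    (0, 14) converges; iteration stops when \\|charge\\| < ``tol``.
    """
    seq = record.sequence
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(200):
        ph = (lo + hi) / 2.0
        q = _net_charge(seq, ph)
        if abs(q) < tol:
            break
        if q > 0:
            lo = ph
        else:
            hi = ph
    return ph


def physicochemical(record: ProteinRecord) -> np.ndarray:
    """24-element scaled physicochemical summary vector.

    Log-scaled molecular weight and length, 19 residue-class fractions,
    isoelectric point / 14, and linearly scaled molecular weight and
    length (titin-scale denominators keep all elements in [0, 1]).
    """
    seq = record.sequence
    n = len(seq)
    mw = molecular_weight(record)
    counts = {aa: seq.count(aa) for aa in STANDARD_RESIDUES}
    out = [np.log10(mw) / 7.0, np.log10(n) / 5.0]
    for _, members in _PHYSCHEM_CLASSES:
        out.append(sum(counts[aa] for aa in members) / n)
    out.append(isoelectric_point(record) / 14.0)
    out.append(mw / 4_000_000.0)
    out.append(n / 38_000.0)
    return np.array(out)


def saac(record: ProteinRecord) -> np.ndarray:
    """Split amino acid composition: AAC of the first 25 residues, the
    central region, and the last 25 residues, concatenated (60 elements)."""
    seq = record.sequence
    if len(seq) < 51:
        raise LengthError(f"saac requires length >= 51, got {len(seq)}")
    return np.concatenate([_aac_str(seq[:25]), _aac_str(seq[25:-25]), _aac_str(seq[-25:])])


def composite_aac_physchem(record: ProteinRecord) -> np.ndarray:
    """44-element concatenation of ``aac`` and ``physchem``."""
    return np.concatenate([aac(record), physicochemical(record)])


# ---------------------------------------------------------------------------
# dispatch / feature naming

_AAC_NAMES = [f"AAC_{aa}" for aa in STANDARD_RESIDUES]
_DIPEP_NAMES = [f"DP_{a}{b}" for a in STANDARD_RESIDUES for b in STANDARD_RESIDUES]
_CT_NAMES = [f"CT_{i+1}.{j+1}.{k+1}" for i, j, k in itertools.product(range(7), repeat=3)]
_CTD_NAMES = (
    [f"C_g{i+1}" for i in range(7)]
    + [f"T_g{i+1}g{j+1}" for i in range(7) for j in range(i + 1, 7)]
    + [f"D_g{i+1}_{q}" for i in range(7) for q in ("first", "25", "50", "75", "100")]
)
_SAAC_NAMES = (
    [f"N_{aa}" for aa in STANDARD_RESIDUES]
    + [f"M_{aa}" for aa in STANDARD_RESIDUES]
    + [f"C_{aa}" for aa in STANDARD_RESIDUES]
)


def _autocorr_names(prefix: str, props: PropertySet, max_lag: int) -> list[str]:
    return [f"{prefix}_{name}_{d}" for name in props.names for d in range(1, max_lag + 1)]


DESCRIPTOR_NAMES = ("aac", "dipep", "ct", "ctd", "moran", "geary", "mba", "physchem", "saac", "composite")

#: Fixed output dimension of each descriptor.
DESCRIPTOR_DIMS = {
    "aac": 20, "dipep": 400, "ct": 343, "ctd": 63,
    "moran": 240, "geary": 240, "mba": 240,
    "physchem": 24, "saac": 60, "composite": 44,
}


def encode(
    records: list[ProteinRecord],
    descriptor: str,
    props: PropertySet | None = None,
    max_lag: int = 30,
) -> FeatureMatrix:
    """Encode records with one descriptor family into a :class:`FeatureMatrix`."""
    if descriptor not in DESCRIPTOR_NAMES:
        raise ValueError(f"unknown descriptor {descriptor!r}; choose from {DESCRIPTOR_NAMES}")
    props = props or default_properties()
    if descriptor == "aac":
        names, fn = _AAC_NAMES, aac
    elif descriptor == "dipep":
        names, fn = _DIPEP_NAMES, dipep
    elif descriptor == "ct":
        names, fn = _CT_NAMES, conjoint_triad
    elif descriptor == "ctd":
        names, fn = _CTD_NAMES, ctd
    elif descriptor == "moran":
        names = _autocorr_names("MAC", props, max_lag)
        fn = lambda r: moran(r, props, max_lag)
    elif descriptor == "geary":
        names = _autocorr_names("GA", props, max_lag)
        fn = lambda r: geary(r, props, max_lag)
    elif descriptor == "mba":
        names = _autocorr_names("MBA", props, max_lag)
        fn = lambda r: moreau_broto(r, props, max_lag)
    elif descriptor == "physchem":
        names, fn = PHYSCHEM_FEATURE_NAMES, physicochemical
    elif descriptor == "saac":
        names, fn = _SAAC_NAMES, saac
    else:  # composite
        names = _AAC_NAMES + PHYSCHEM_FEATURE_NAMES
        fn = composite_aac_physchem
    values = np.vstack([fn(r) for r in records]) if records else np.empty((0, len(names)))
    return FeatureMatrix(
        descriptor_name=descriptor,
        row_ids=tuple(r.id for r in records),
        feature_names=tuple(names),
        values=values,
    )
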