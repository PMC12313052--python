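"""Potts fitness landscape: energies, mutation-effect scores, couplings.

The landscape is a pairwise (Potts) statistical model over amino-acid
sequences with per-site fields ``h`` and pairwise couplings ``J``.  Its
statistical energy

    E(sigma) = sum_i h_i(sigma_i) + sum_{i<j} J_ij(sigma_i, sigma_j)

is oriented so that *higher* energy means *higher predicted fitness*: the
mutation-effect ("epistatic") score of a variant is E(mutant) - E(wild type),
positive for substitutions the model predicts to be beneficial.  An
:class:`IndependentModel` carries site-wise terms only and yields the
couplings-blind ("independent") score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "PROTEIN_ALPHABET",
    "PottsModel",
    "IndependentModel",
    "Mutation",
    "VariantGenotype",
    "potts_energy",
    "epistatic_score",
    "independent_score",
    "coupling_strength",
    "coupling_matrix",
    "read_model",
    "write_model",
]


@dataclass(frozen=True)
class Mutation:
    """A single amino-acid exchange in model coordinates (1-based)."""

    position: int
    wt_symbol: str
    mut_symbol: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.wt_symbol == self.mut_symbol:
            raise ValueError(f"mutation at {self.position} does not change the symbol")

    @property
    def label(self) -> str:
        return f"{self.wt_symbol}{self.position}{self.mut_symbol}"

    def residue_label(self, numbering_offset: int) -> str:
        """Label in protein residue numbering (model position + offset)."""
        return f"{self.wt_symbol}{self.position + numbering_offset}{self.mut_symbol}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class VariantGenotype:
    """A set of single-site exchanges relative to the wild type."""

    mutations: tuple[Mutation, ...]
    label: str = ""
    barcode: str | None = None

    def __post_init__(self) -> None:
        muts = tuple(sorted(self.mutations, key=lambda m: m.position))
        positions = [m.position for m in muts]
        if len(set(positions)) != len(positions):
            raise ValueError(f"duplicate mutated positions: {positions}")
        object.__setattr__(self, "mutations", muts)
        if self.barcode is not None and set(self.barcode) - set("ACGT"):
            raise ValueError(f"barcode contains non-ACGT symbols: {self.barcode!r}")
        if not self.label:
            object.__setattr__(
                self, "label", "+".join(m.label for m in muts) if muts else "WT"
            )

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    def apply_to(self, wt_sequence: str) -> str:
        """Return the mutant sequence obtained from ``wt_sequence``."""
        seq = list(wt_sequence)
        for m in self.mutations:
            if seq[m.position - 1] != m.wt_symbol:
                raise ValueError(
                    f"mutation {m.label}: wild type has "
                    f"{seq[m.position - 1]!r} at position {m.position}"
                )
            seq[m.position - 1] = m.mut_symbol
        return "".join(seq)


def _check_symmetry(J: np.ndarray, atol: float = 1e-8) -> None:
    if not np.allclose(J, J.transpose(1, 0, 3, 2), atol=atol):
        raise ValueError("couplings J are not symmetric under (i,j),(a,b) swap")


@dataclass
class PottsModel:
    """Fields, couplings and wild-type sequence of a Potts landscape.

    Parameters
    ----------
    alphabet
        Ordered symbol string; defaults to the 20 canonical residues.
    h
        Fields, shape ``(L, q)``.
    J
        Couplings, shape ``(L, L, q, q)`` with ``J[i, j, a, b] == J[j, i, b, a]``
        and zero diagonal blocks.
    wt_sequence
        Length-``L`` reference sequence over ``alphabet``.
    numbering_offset
        Added to 1-based model positions to obtain protein residue numbers
        (e.g. to skip an N-terminal purification tag).
    """

    h: np.ndarray
    J: np.ndarray
    wt_sequence: str
    alphabet: str = PROTEIN_ALPHABET
    numbering_offset: int = 0
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError(f"J shape {self.J.shape} incompatible with h {self.h.shape}")
        if len(self.alphabet) != q:
            raise ValueError(f"alphabet length {len(self.alphabet)} != q = {q}")
        if len(self.wt_sequence) != L:
            raise ValueError(f"wt_sequence length {len(self.wt_sequence)} != L = {L}")
        if not (np.isfinite(self.h).all() and np.isfinite(self.J).all()):
            raise ValueError("non-finite model parameters")
        _check_symmetry(self.J)
        self.J[np.arange(L), np.arange(L)] = 0.0
        self._index = {s: k for k, s in enumerate(self.alphabet)}
        bad = set(self.wt_sequence) - set(self.alphabet)
        if bad:
            raise ValueError(f"wild-type symbols outside alphabet: {sorted(bad)}")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    def encode(self, sequence: str) -> np.ndarray:
        """Encode a sequence as integer symbol indices; validates symbols."""
        if len(sequence) != self.L:
            raise ValueError(f"sequence length {len(sequence)} != model L = {self.L}")
        try:
            return np.array([self._index[s] for s in sequence], dtype=np.int64)
        except KeyError:
            for pos, s in enumerate(sequence, start=1):
                if s not in self._index:
                    raise ValueError(
                        f"symbol {s!r} at position {pos} not in alphabet"
                    ) from None
            raise  # pragma: no cover

    def decode(self, encoded: np.ndarray) -> str:
        return "".join(self.alphabet[k] for k in encoded)

    def wt_encoded(self) -> np.ndarray:
        return self.encode(self.wt_sequence)

    def validate_variant(self, variant: VariantGenotype) -> None:
        for m in variant.mutations:
            if not 1 <= m.position <= self.L:
                raise ValueError(f"mutation {m.label}: position outside 1..{self.L}")
            if self.wt_sequence[m.position - 1] != m.wt_symbol:
                raise ValueError(
                    f"mutation {m.label}: model wild type has "
                    f"{self.wt_sequence[m.position - 1]!r} at position {m.position}"
                )
            if m.mut_symbol not in self._index:
                raise ValueError(f"mutation {m.label}: symbol not in alphabet")


@dataclass
class IndependentModel:
    """Site-independent companion model (fields only, no couplings)."""

    fields: np.ndarray
    wt_sequence: str
    alphabet: str = PROTEIN_ALPHABET

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=float)
        L, q = self.fields.shape
        if len(self.alphabet) != q:
            raise ValueError(f"alphabet length {len(self.alphabet)} != q = {q}")
        if len(self.wt_sequence) != L:
            raise ValueError(f"wt_sequence length {len(self.wt_sequence)} != L = {L}")
        if not np.isfinite(self.fields).all():
            raise ValueError("non-finite fields")
        self._index = {s: k for k, s in enumerate(self.alphabet)}

    @property
    def L(self) -> int:
        return self.fields.shape[0]


def potts_energy(model: PottsModel, sequence: str | np.ndarray) -> float:
    """Statistical energy E(sigma) = sum h + sum_{i<j} J (higher = fitter)."""
    s = model.encode(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    L = model.L
    idx = np.arange(L)
    field_term = model.h[idx, s].sum()
    pair = model.J[idx[:, None], idx[None, :], s[:, None], s[None, :]]
    return float(field_term + 0.5 * pair.sum())


def epistatic_score(model: PottsModel, variant: VariantGenotype) -> float:
    """Couplings-aware mutation-effect score: E(mutant) - E(wild type)."""
    model.validate_variant(variant)
    if not variant.mutations:
        return 0.0
    wt = model.wt_encoded()
    mut = wt.copy()
    for m in variant.mutations:
        mut[m.position - 1] = model._index[m.mut_symbol]
    return potts_energy(model, mut) - potts_energy(model, wt)


def independent_score(imodel: IndependentModel, variant: VariantGenotype) -> float:
    """Site-independent score: sum over mutated sites of field differences."""
    total = 0.0
    for m in variant.mutations:
        if not 1 <= m.position <= imodel.L:
            raise ValueError(f"mutation {m.label}: position outside 1..{imodel.L}")
        if imodel.wt_sequence[m.position - 1] != m.wt_symbol:
            raise ValueError(
                f"mutation {m.label}: wild type has "
                f"{imodel.wt_sequence[m.position - 1]!r} at position {m.position}"
            )
        i = m.position - 1
        total += imodel.fields[i, imodel._index[m.mut_symbol]]
        total -= imodel.fields[i, imodel._index[m.wt_symbol]]
    return float(total)


def _zero_sum_gauge(block: np.ndarray) -> np.ndarray:
    return (
        block
        - block.mean(axis=0, keepdims=True)
        - block.mean(axis=1, keepdims=True)
        + block.mean()
    )


def coupling_matrix(model: PottsModel, apc: bool = True) -> np.ndarray:
    """Pairwise coupling-strength matrix.

    Each ``q x q`` coupling block is moved to the zero-sum gauge, reduced to
    its Frobenius norm, and the average-product correction (APC) subtracted —
    the standard contact-ranking pipeline.  APC-corrected values are clipped
    at zero so that strengths are non-negative.
    """
    L = model.L
    F = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            F[i, j] = F[j, i] = np.linalg.norm(_zero_sum_gauge(model.J[i, j]))
    if not apc:
        return F
    off = ~np.eye(L, dtype=bool)
    total_mean = F[off].mean() if L > 1 else 0.0
    if total_mean == 0.0:
        return F
    row_mean = F.sum(axis=1) / (L - 1)
    corrected = F - np.outer(row_mean, row_mean) / total_mean
    corrected[~off] = 0.0
    return np.clip(corrected, 0.0, None)


def coupling_strength(model: PottsModel, i: int, j: int) -> float:
    """APC-corrected coupling strength of position pair ``(i, j)``, 1-based."""
    if i == j:
        raise ValueError("coupling strength undefined for i == j")
    for p in (i, j):
        if not 1 <= p <= model.L:
            raise ValueError(f"position {p} outside 1..{model.L}")
    return float(coupling_matrix(model)[i - 1, j - 1])


# ---------------------------------------------------------------------------
# plain-text model serialization
#
# Header lines:  L <int> / ALPHABET <str> / WT <str> / OFFSET <int>
# Records:       H <pos> <symbol> <value>
#                J <i> <j> <sym_a> <sym_b> <value>
# Positions are 1-based; omitted entries are zero; J records may be given for
# one orientation only and are symmetrized on read.


def write_model(model: PottsModel, path, imodel: IndependentModel | None = None) -> None:
    """Write a model (and optional independent companion) as structured text.

    Zero couplings are omitted; ``write_model`` then ``read_model`` round-trips
    all parameters up to float formatting (repr precision, i.e. exactly).
    """
    with open(path, "w") as fh:
        fh.write("# Potts landscape parameter file\n")
        fh.write(f"L {model.L}\n")
        fh.write(f"ALPHABET {model.alphabet}\n")
        fh.write(f"WT {model.wt_sequence}\n")
        fh.write(f"OFFSET {model.numbering_offset}\n")
        for i in range(model.L):
            for a in range(model.q):
                if model.h[i, a] != 0.0:
                    fh.write(f"H {i + 1} {model.alphabet[a]} {float(model.h[i, a])!r}\n")
        for i in range(model.L):
            for j in range(i + 1, model.L):
                block = model.J[i, j]
                for a, b in zip(*np.nonzero(block)):
                    fh.write(
                        f"J {i + 1} {j + 1} {model.alphabet[a]} "
                        f"{model.alphabet[b]} {float(block[a, b])!r}\n"
                    )
        if imodel is not None:
            for i in range(imodel.L):
                for a in range(imodel.fields.shape[1]):
                    if imodel.fields[i, a] != 0.0:
                        fh.write(
                            f"F {i + 1} {imodel.alphabet[a]} "
                            f"{float(imodel.fields[i, a])!r}\n"
                        )


class ModelParseError(ValueError):
    pass


def read_model(path, with_independent: bool = False):
    """Parse a plain-text Potts parameter file.

    Returns a :class:`PottsModel`, or ``(PottsModel, IndependentModel)`` when
    ``with_independent`` is set and ``F`` records are present.  Structural
    problems raise :class:`ModelParseError` naming the offending line.
    """
    header: dict[str, str] = {}
    records: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            key = parts[0].upper()
            if key in ("L", "ALPHABET", "WT", "OFFSET"):
                if len(parts) != 2:
                    raise ModelParseError(f"line {lineno}: malformed header {line!r}")
                header[key] = parts[1]
            elif key in ("H", "J", "F"):
                records.append((lineno, parts))
            else:
                raise ModelParseError(f"line {lineno}: unknown record type {key!r}")

    for required in ("L", "ALPHABET", "WT"):
        if required not in header:
            raise ModelParseError(f"missing required header field {required}")
    L = int(header["L"])
    alphabet = header["ALPHABET"]
    wt = header["WT"]
    offset = int(header.get("OFFSET", "0"))
    if len(wt) != L:
        raise ModelParseError(f"WT length {len(wt)} does not match L = {L}")
    q = len(alphabet)
    index = {s: k for k, s in enumerate(alphabet)}

    h = np.zeros((L, q))
    J = np.zeros((L, L, q, q))
    Jseen = np.zeros((L, L, q, q), dtype=bool)
    fields = np.zeros((L, q))
    has_fields = False

    def _pos(tok: str, lineno: int) -> int:
        p = int(tok)
        if not 1 <= p <= L:
            raise ModelParseError(f"line {lineno}: position {p} outside 1..{L}")
        return p - 1

    def _sym(tok: str, lineno: int) -> int:
        if tok not in index:
            raise ModelParseError(f"line {lineno}: symbol {tok!r} not in alphabet")
        return index[tok]

    for lineno, parts in records:
        key = parts[0].upper()
        try:
            if key in ("H", "F"):
                if len(parts) != 4:
                    raise ModelParseError(f"line {lineno}: malformed {key} record")
                i, a, v = _pos(parts[1], lineno), _sym(parts[2], lineno), float(parts[3])
                if key == "H":
                    h[i, a] = v
                else:
                    fields[i, a] = v
                    has_fields = True
            else:
                if len(parts) != 6:
                    raise ModelParseError(f"line {lineno}: malformed J record")
                i, j = _pos(parts[1], lineno), _pos(parts[2], lineno)
                a, b = _sym(parts[3], lineno), _sym(parts[4], lineno)
                v = float(parts[5])
                if i == j:
                    raise ModelParseError(f"line {lineno}: J record with i == j")
                if Jseen[i, j, a, b] and J[i, j, a, b] != v:
                    raise ModelParseError(
                        f"line {lineno}: conflicting J value for "
                        f"({i + 1},{j + 1},{parts[3]},{parts[4]})"
                    )
                J[i, j, a, b] = v
                Jseen[i, j, a, b] = True
                if Jseen[j, i, b, a] and J[j, i, b, a] != v:
                    raise ModelParseError(
                        f"line {lineno}: J record asymmetric with earlier "
                        f"({j + 1},{i + 1}) record"
                    )
                J[j, i, b, a] = v
                Jseen[j, i, b, a] = True
        except ValueError as exc:
            if isinstance(exc, ModelParseError):
                raise
            raise ModelParseError(f"line {lineno}: {exc}") from None

    model = PottsModel(h=h, J=J, wt_sequence=wt, alphabet=alphabet, numbering_offset=offset)
    if with_independent:
        imodel = (
            IndependentModel(fields=fields, wt_sequence=wt, alphabet=alphabet)
            if has_fields
            else None
        )
        return model, imodel
    return model


def all_single_mutants(model: PottsModel):
    """Iterate over every single-site exchange of the wild type."""
    for i, wt_sym in enumerate(model.wt_sequence, start=1):
        for sym in model.alphabet:
            if sym != wt_sym:
                yield Mutation(i, wt_sym, sym)
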