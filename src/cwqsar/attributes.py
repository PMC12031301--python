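"""SMILES tokenization and attribute extraction.

The method treats a SMILES string as a plain character sequence and derives
local structural attributes from it — no chemistry perception is involved.
Five attribute families are extracted:

``Sk``
    single tokens (one SMILES "atom", where multi-character units such as
    ``Cl``, ``Br``, ``@@``, ``%NN`` ring closures and bracket atoms
    ``[...]`` count as one token);
``SSk`` / ``SSSk``
    adjacent token pairs / triples, canonicalized so that reading the
    string backwards yields the same attribute multiset;
``FLS``
    fragments of local symmetry — token windows of shape XYX, XYYX or
    XYZYX with X != Y (and Y != Z for XYZYX);
``APP``
    atom-pair proportions — for each pair of element tokens present, the
    ratio of their counts discretized to ten levels.

Each molecule becomes an :class:`AttributeBag`, a multiset of attribute
keys.  Correlation weights are later attached to these keys; the sum of
weights over a molecule's bag is the optimal descriptor.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import ConfigurationError, InvalidInputError, MalformedSmilesError

# Token is a plain string: one SMILES symbol or a multi-character unit.
Token = str

#: two-character units that are never split
_TWO_CHAR_TOKENS = ("Cl", "Br", "@@")

#: default element vocabulary for atom-pair proportions
DEFAULT_APP_VOCAB: tuple[str, ...] = (
    "C", "c", "N", "n", "O", "o", "S", "s", "P", "F", "Cl", "Br", "I",
)

SK = "Sk"
SSK = "SSk"
SSSK = "SSSk"
FLS = "FLS"
APP = "APP"

FAMILIES = (SK, SSK, SSSK, FLS, APP)


@dataclass(frozen=True)
class AttributeConfig:
    """Which attribute families participate, and how they are keyed.

    Parameters
    ----------
    use_sk, use_ssk, use_sssk, use_fls, use_app
        Family toggles; all enabled by default.
    app_vocab
        Element tokens counted for atom-pair proportions.
    fls_content
        If False (default), local-symmetry fragments are keyed only by their
        pattern class (``[xyx0]``, ``[xyyx0]``, ``[xyzyx0]``); if True the
        key also records the tokens involved.
    """

    use_sk: bool = True
    use_ssk: bool = True
    use_sssk: bool = True
    use_fls: bool = True
    use_app: bool = True
    app_vocab: tuple[str, ...] = DEFAULT_APP_VOCAB
    fls_content: bool = False

    def enabled_families(self) -> tuple[str, ...]:
        flags = {
            SK: self.use_sk,
            SSK: self.use_ssk,
            SSSK: self.use_sssk,
            FLS: self.use_fls,
            APP: self.use_app,
        }
        return tuple(f for f in FAMILIES if flags[f])


@dataclass
class AttributeBag:
    """Multiset of attribute keys extracted from one SMILES string."""

    keys: Counter = field(default_factory=Counter)
    families: dict[str, str] = field(default_factory=dict)

    def add(self, key: str, family: str, count: int = 1) -> None:
        self.keys[key] += count
        self.families[key] = family

    def merge(self, other: "AttributeBag") -> "AttributeBag":
        out = AttributeBag(Counter(self.keys), dict(self.families))
        out.keys.update(other.keys)
        out.families.update(other.families)
        return out

    def family_keys(self, family: str) -> Counter:
        return Counter(
            {k: c for k, c in self.keys.items() if self.families[k] == family}
        )

    def __len__(self) -> int:
        return sum(self.keys.values())


def tokenize(smiles: str) -> list[Token]:
    """Split a SMILES string into its token sequence, losslessly.

    ``Cl``, ``Br``, ``@@`` and ``%`` followed by two digits are single
    tokens; a bracket expression ``[...]`` is one token; every other
    character stands alone.  Concatenating the result reproduces the input.

    Raises
    ------
    InvalidInputError
        for an empty string.
    MalformedSmilesError
        for an unclosed ``[`` or a ``%`` not followed by two digits.
    """
    if not smiles:
        raise InvalidInputError("empty SMILES string")
    tokens: list[Token] = []
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise MalformedSmilesError(f"unclosed '[' at position {i}")
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise MalformedSmilesError(
                    f"'%' at position {i} not followed by two digits"
                )
            tokens.append(smiles[i : i + 3])
            i += 3
        elif smiles[i : i + 2] in _TWO_CHAR_TOKENS:
            tokens.append(smiles[i : i + 2])
            i += 2
        else:
            tokens.append(ch)
            i += 1
    return tokens


def pair_key(a: Token, b: Token) -> str:
    """Canonical key of an adjacent token pair (direction-independent)."""
    lo, hi = sorted((a, b))
    return f"{lo}|{hi}"


def triple_key(a: Token, b: Token, c: Token) -> str:
    """Canonical key of an adjacent token triple: middle fixed, ends sorted."""
    lo, hi = sorted((a, c))
    return f"{lo}|{b}|{hi}"


def extract_pairs_triples(tokens: list[Token]) -> AttributeBag:
    """Canonical pair (SSk) and triple (SSSk) attributes of a token list.

    Sequences shorter than the window emit nothing for that family, so a
    single-token molecule yields an empty bag.
    """
    bag = AttributeBag()
    for a, b in zip(tokens, tokens[1:]):
        bag.add(pair_key(a, b), SSK)
    for a, b, c in zip(tokens, tokens[1:], tokens[2:]):
        bag.add(triple_key(a, b, c), SSSK)
    return bag


_FLS_CLASSES = ("xyx0", "xyyx0", "xyzyx0")


def _fls_key(cls: str, content: tuple[Token, ...] | None) -> str:
    if content is None:
        return f"[{cls}]"
    return f"[{cls}:" + "|".join(content) + "]"


def detect_fls(tokens: list[Token], *, content: bool = False) -> list[str]:
    """Fragments of local symmetry: windows matching XYX, XYYX or XYZYX.

    The patterns require X != Y (and additionally Y != Z for XYZYX); a run
    of identical tokens is therefore not locally symmetric.  By default the
    key records only the pattern class; with ``content=True`` it also
    records which tokens realize it.
    """
    found: list[str] = []
    n = len(tokens)
    for i in range(n - 2):
        x, y, z = tokens[i : i + 3]
        if x == z and x != y:
            found.append(_fls_key("xyx0", (x, y) if content else None))
    for i in range(n - 3):
        a, b, c, d = tokens[i : i + 4]
        if a == d and b == c and a != b:
            found.append(_fls_key("xyyx0", (a, b) if content else None))
    for i in range(n - 4):
        a, b, c, d, e = tokens[i : i + 5]
        if a == e and b == d and a != b and b != c:
            found.append(_fls_key("xyzyx0", (a, b, c) if content else None))
    return found


def extract_app(
    tokens: list[Token], vocab: tuple[str, ...] = DEFAULT_APP_VOCAB
) -> list[str]:
    """Atom-pair proportion attributes.

    For each unordered pair (X, Y) of vocabulary elements both present in
    the molecule, the count ratio min/max is discretized to r in 1..10 and
    keyed as ``APP(X,Y,r)``.  Equal counts give r = 10; a pair needs two
    distinct elements, so a one-element molecule emits nothing.
    """
    if not vocab:
        raise ConfigurationError("APP vocabulary must be non-empty")
    counts = Counter(t for t in tokens if t in vocab)
    present = sorted(counts)
    keys: list[str] = []
    for i, x in enumerate(present):
        for y in present[i + 1 :]:
            nx, ny = counts[x], counts[y]
            r = max(1, round(10 * min(nx, ny) / max(nx, ny)))
            keys.append(f"APP({x},{y},{r})")
    return keys


def extract_attributes(
    smiles: str, config: AttributeConfig | None = None
) -> AttributeBag:
    """Extract the full attribute bag of one SMILES string.

    Families are individually switchable through ``config``; with every
    family disabled the bag is empty.  Tokenization errors propagate.
    """
    cfg = config or AttributeConfig()
    tokens = tokenize(smiles)
    bag = AttributeBag()
    if cfg.use_sk:
        for t in tokens:
            bag.add(t, SK)
    if cfg.use_ssk or cfg.use_sssk:
        pt = extract_pairs_triples(tokens)
        for key, c in pt.keys.items():
            fam = pt.families[key]
            if (fam == SSK and cfg.use_ssk) or (fam == SSSK and cfg.use_sssk):
                bag.add(key, fam, c)
    if cfg.use_fls:
        for key in detect_fls(tokens, content=cfg.fls_content):
            bag.add(key, FLS)
    if cfg.use_app:
        for key in extract_app(tokens, cfg.app_vocab):
            bag.add(key, APP)
    return bag
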