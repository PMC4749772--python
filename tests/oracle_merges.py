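"""Independent brute-force re-derivation of merge Rules 1-4.

Used as the cross-check oracle for the tokenizer's single-pass merge
implementation. Works on plain ``(surface, start, end)`` triples, merges by
repeatedly searching the whole sequence for the leftmost applicable merge
(Rules 1-3) or by recursive longest-first window enumeration (Rule 4) — a
deliberately naive route that shares no code with the package's pipeline.
"""

from __future__ import annotations

Tok = tuple[str, int, int]

_DIGITS = set("0123456789")


def _numeric(s: str) -> bool:
    return bool(s) and all(c in _DIGITS for c in s)


def _is_chain(s: str, seps: frozenset[str]) -> bool:
    """digits, optionally repeated as digits-sep-digits-..."""
    i, n = 0, len(s)
    while True:
        j = i
        while j < n and s[j] in _DIGITS:
            j += 1
        if j == i:
            return False
        if j == n:
            return True
        if s[j] not in seps:
            return False
        i = j + 1


def _contig(a: Tok, b: Tok) -> bool:
    return a[2] == b[1]


def _merge(toks: list[Tok]) -> Tok:
    return "".join(t[0] for t in toks), toks[0][1], toks[-1][2]


def oracle_rule1(toks: list[Tok], seps: frozenset[str]) -> list[Tok]:
    toks = list(toks)
    while True:
        found = None
        for i in range(len(toks)):
            if not _numeric(toks[i][0]):
                continue
            j = i
            while (
                j + 2 < len(toks)
                and len(toks[j + 1][0]) == 1
                and toks[j + 1][0] in seps
                and _numeric(toks[j + 2][0])
                and _contig(toks[j], toks[j + 1])
                and _contig(toks[j + 1], toks[j + 2])
            ):
                j += 2
            if j > i:
                found = (i, j)
                break
        if found is None:
            return toks
        i, j = found
        toks[i : j + 1] = [_merge(toks[i : j + 1])]


def oracle_rule2(
    toks: list[Tok], seps: frozenset[str], containers: tuple[tuple[str, str], ...]
) -> list[Tok]:
    closer = dict(containers)
    toks = list(toks)
    while True:
        found = None
        for i in range(len(toks) - 2):
            if (
                toks[i][0] in closer
                and toks[i + 2][0] == closer[toks[i][0]]
                and _is_chain(toks[i + 1][0], seps)
                and _contig(toks[i], toks[i + 1])
                and _contig(toks[i + 1], toks[i + 2])
            ):
                found = i
                break
        if found is None:
            return toks
        toks[found : found + 3] = [_merge(toks[found : found + 3])]


def oracle_rule3(toks: list[Tok]) -> list[Tok]:
    toks = list(toks)
    while True:
        found = None
        for i in range(len(toks) - 1):
            a, b = toks[i][0], toks[i + 1][0]
            if (
                len(a) == 1
                and a.isascii() and a.isalpha() and a.isupper()
                and b.isascii() and b.isalpha() and b.islower()
                and _contig(toks[i], toks[i + 1])
            ):
                found = i
                break
        if found is None:
            return toks
        toks[found : found + 2] = [_merge(toks[found : found + 2])]


def oracle_rule4(toks: list[Tok], names_folded: set[str], window: int) -> list[Tok]:
    if not toks:
        return []
    for w in range(min(window, len(toks)), 1, -1):
        head = toks[:w]
        if all(_contig(head[k], head[k + 1]) for k in range(w - 1)) and "".join(
            t[0] for t in head
        ).casefold() in names_folded:
            return [_merge(head)] + oracle_rule4(toks[w:], names_folded, window)
    return [toks[0]] + oracle_rule4(toks[1:], names_folded, window)


def oracle_rules_1_4(
    toks: list[Tok],
    names: set[str],
    seps: frozenset[str] = frozenset({".", ",", "/", "-", "_"}),
    containers: tuple[tuple[str, str], ...] = (("(", ")"), ("[", "]"), ("{", "}")),
    window: int = 5,
) -> list[Tok]:
    folded = {n.casefold() for n in names}
    toks = oracle_rule1(toks, seps)
    toks = oracle_rule2(toks, seps, containers)
    toks = oracle_rule3(toks)
    return oracle_rule4(toks, folded, window)
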