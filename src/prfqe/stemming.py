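"""The original (1980) Porter stemming algorithm.

A self-contained implementation of Porter's suffix-stripping algorithm as
published, without the later "Porter2/English" revisions: step 2 maps
``abli -> able`` and there is no ``logi -> log`` rule.  Words of length one
or two are returned unchanged.  Conditions (the measure m, *v*, *d and *o)
are evaluated on the stem remaining after the candidate suffix is removed,
and within each step only the longest matching suffix is considered.
"""

from __future__ import annotations

__all__ = ["porter_stem_word"]

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return True if i == 0 else not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences: [C](VC){m}[V]."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        if _is_cons(stem, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(stem: str) -> bool:
    return (
        len(stem) >= 2
        and stem[-1] == stem[-2]
        and _is_cons(stem, len(stem) - 1)
    )


def _cvc(stem: str) -> bool:
    """consonant-vowel-consonant ending, final consonant not w, x or y."""
    if len(stem) < 3:
        return False
    return (
        _is_cons(stem, len(stem) - 3)
        and not _is_cons(stem, len(stem) - 2)
        and _is_cons(stem, len(stem) - 1)
        and stem[-1] not in "wxy"
    )


# (suffix, replacement) pairs; within a step the longest matching suffix wins.
_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)
_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)
_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def _longest_rule(word: str, rules) -> tuple[str, str] | None:
    best = None
    for suf, rep in rules:
        if word.endswith(suf) and (best is None or len(suf) > len(best[0])):
            best = (suf, rep)
    return best


def porter_stem_word(word: str) -> str:
    if len(word) <= 2:
        return word
    w = word

    # Step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # Step 1b
    cleanup = False
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    elif w.endswith("ed") and _has_vowel(w[:-2]):
        w = w[:-2]
        cleanup = True
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        w = w[:-3]
        cleanup = True
    if cleanup:
        if w.endswith(("at", "bl", "iz")):
            w += "e"
        elif _ends_double_cons(w) and w[-1] not in "lsz":
            w = w[:-1]
        elif _measure(w) == 1 and _cvc(w):
            w += "e"

    # Step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # Step 2
    rule = _longest_rule(w, _STEP2)
    if rule is not None:
        suf, rep = rule
        if _measure(w[: -len(suf)]) > 0:
            w = w[: -len(suf)] + rep

    # Step 3
    rule = _longest_rule(w, _STEP3)
    if rule is not None:
        suf, rep = rule
        if _measure(w[: -len(suf)]) > 0:
            w = w[: -len(suf)] + rep

    # Step 4
    rule = _longest_rule(w, tuple((s, "") for s in _STEP4))
    if rule is not None:
        suf, _ = rule
        base = w[: -len(suf)]
        if _measure(base) > 1 and (suf != "ion" or (base and base[-1] in "st")):
            w = base

    # Step 5a
    if w.endswith("e"):
        base = w[:-1]
        m = _measure(base)
        if m > 1 or (m == 1 and not _cvc(base)):
            w = base

    # Step 5b
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]

    return w
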