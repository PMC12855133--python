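"""Independent token-replay oracle, written from first principles.

This simulator is deliberately naive and structurally different from the
package's counter-based implementation: the marking is a literal bag of
token objects (a list of place names), transitions are resolved through a
freshly built label index, and every produce/consume is an explicit list
operation. It exists only to cross-check fitness values; tests compare the
two routes and must never share code with the implementation under test.
"""

from __future__ import annotations


def naive_replay(labels: list[str], net_description: dict) -> dict:
    """Replay a label sequence over a net given as a plain JSON-style dict.

    ``net_description`` uses the documented net-interchange schema:
    {"places": [...], "transitions": [{"id", "label"}, ...],
     "arcs": [[from, to], ...], "source": ..., "sink": ...}.
    Returns {"p", "c", "m", "r", "fitness"}.
    """
    places = set(net_description["places"])
    label_of = {t["id"]: t["label"] for t in net_description["transitions"]}
    by_label: dict[str, str] = {}
    for tid in sorted(label_of):
        by_label.setdefault(label_of[tid], tid)
    in_places: dict[str, list[str]] = {tid: [] for tid in label_of}
    out_places: dict[str, list[str]] = {tid: [] for tid in label_of}
    for src, dst in net_description["arcs"]:
        if src in places:
            in_places[dst].append(src)
        else:
            out_places[src].append(dst)

    tokens: list[str] = []  # the marking, one entry per token
    produced = consumed = missing = 0

    tokens.append(net_description["source"])
    produced += 1

    for label in labels:
        tid = by_label.get(label)
        if tid is None:
            continue  # unmapped activity: skipped, matching lenient mode
        for place in sorted(in_places[tid]):
            if place not in tokens:
                tokens.append(place)
                missing += 1
            tokens.remove(place)
            consumed += 1
        for place in sorted(out_places[tid]):
            tokens.append(place)
            produced += 1

    sink = net_description["sink"]
    if sink not in tokens:
        tokens.append(sink)
        missing += 1
    tokens.remove(sink)
    consumed += 1

    remaining = len(tokens)
    fitness = 0.5 * (1.0 - missing / consumed) + 0.5 * (1.0 - remaining / produced)
    return {"p": produced, "c": consumed, "m": missing, "r": remaining, "fitness": fitness}
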