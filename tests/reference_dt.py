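"""Naive pure-Python forward-scan reference for the bedrest decision tree.

A literal transcription of the documented four-step procedure, written
with plain loops and no array indexing tricks, used only as an oracle for
equivalence testing of the production detector.
"""

BEDREST = 0
WAKE = 1


def naive_block_means(x, block_length):
    means = []
    i = 0
    while i < len(x):
        block = x[i : i + block_length]
        means.append(sum(block) / len(block))
        i += block_length
    return means


def naive_detect(x, block_length, threshold, start_trigger, end_trigger, min_bedrest_epochs):
    """Label a single worn segment; returns a list of BEDREST/WAKE ints."""
    n = len(x)
    means = naive_block_means(x, block_length)
    labels = [None] * n
    status = BEDREST if means[0] <= threshold else WAKE
    pos = 0
    seen = set()
    while pos < n:
        if (status, pos) in seen:
            labels[pos] = status
            pos += 1
            continue
        seen.add((status, pos))
        if status == WAKE:
            boundary = None
            for k in range(pos // block_length, len(means)):
                if means[k] < threshold:
                    lo = (k - 1) * block_length if k >= 1 else 0
                    lo = max(lo, pos)
                    hi = min((k + 1) * block_length, n)
                    last_pair = None
                    for i in range(lo, hi - 1):
                        if x[i] > start_trigger and x[i + 1] > start_trigger:
                            last_pair = i
                    if last_pair is not None:
                        boundary = last_pair + 2
                    else:
                        boundary = max(k * block_length, pos)
                    break
            if boundary is None:
                for i in range(pos, n):
                    labels[i] = WAKE
                break
            for i in range(pos, boundary):
                labels[i] = WAKE
            pos, status = boundary, BEDREST
        else:
            boundary = None
            for k in range(pos // block_length, len(means)):
                if means[k] > threshold:
                    lo = (k - 1) * block_length if k >= 1 else 0
                    lo = max(lo, pos)
                    hi = min((k + 1) * block_length, n)
                    first_pair = None
                    for i in range(lo, hi - 1):
                        if x[i] > end_trigger and x[i + 1] > end_trigger:
                            first_pair = i
                            break
                    if first_pair is not None:
                        boundary = first_pair
                    else:
                        boundary = max(k * block_length, pos)
                    break
            if boundary is None:
                for i in range(pos, n):
                    labels[i] = BEDREST
                break
            for i in range(pos, boundary):
                labels[i] = BEDREST
            pos, status = boundary, WAKE

    # Step 4: demote bedrest runs shorter than the minimum.
    i = 0
    while i < n:
        if labels[i] == BEDREST:
            j = i
            while j < n and labels[j] == BEDREST:
                j += 1
            if j - i < min_bedrest_epochs:
                for k in range(i, j):
                    labels[k] = WAKE
            i = j
        else:
            i += 1
    return labels
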