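"""Resolve the TAD context of a breakpoint.

Builds the synthetic annotation universe, then asks which TAD a breakpoint
falls in (the brTAD) and for its flanking TADs, plus the average-size
window fallback used for chromosomes without called TADs.
"""
import tempfile

import tadsv
import tadsv.io as tio
from tadsv import fixtures
from tadsv.regions import TADMap, chry_fallback_window, flanking_tads, resolve_brtad

with tempfile.TemporaryDirectory() as tmp:
    manifest = fixtures.make_toy_genome(tmp, seed=7)
    tads = TADMap(tio.read_tads(manifest.files["tads"], "hESC"))

    bp = tadsv.Breakpoint("chr1", 150_000)
    br = resolve_brtad(bp, tads)
    print(f"breakpoint {bp.chrom}:{bp.pos + 1} falls in TAD "
          f"[{br.interval.start:,}-{br.interval.end:,})")
    # the brTAD is the unit within which regulatory consequences are assessed

    for flank in flanking_tads(bp, tads, k=2):
        print(f"  TAD{flank.offset:+d}: [{flank.interval.start:,}-{flank.interval.end:,})")
    # offsets -2..+2 are the neighbouring TADs in coordinate order,
    # truncated at chromosome ends

    y = chry_fallback_window(tadsv.Breakpoint("chrY", 1_000_000), avg_size=815_000)
    print(f"chrY fallback window (815 kb average TAD size): "
          f"[{y.interval.start:,}-{y.interval.end:,})")
    # chromosomes without called TADs use fixed-size windows instead
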