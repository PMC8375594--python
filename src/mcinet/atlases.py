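"""Region orderings for the two parcellations used by the pipeline.

Structural features live on the 68-region Desikan-Killiany cortical
parcellation (34 regions per hemisphere, left hemisphere first), functional
features on the 90-region AAL parcellation in its canonical numbering
(cerebrum only, left/right interleaved).

The Desikan-Killiany ordering follows the FreeSurfer ``aparc`` statistics
convention: alphabetical, with frontalpole, temporalpole, transversetemporal
and insula appended at the end of each hemisphere block.
"""

from __future__ import annotations

# FreeSurfer aparc order of the 34 Desikan-Killiany regions per hemisphere.
DK_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

_DK_ABBREV: dict[str, str] = {
    "bankssts": "BSTS",
    "caudalanteriorcingulate": "CACC",
    "caudalmiddlefrontal": "CMF",
    "cuneus": "CUN",
    "entorhinal": "ENT",
    "fusiform": "FUS",
    "inferiorparietal": "IPL",
    "inferiortemporal": "ITG",
    "isthmuscingulate": "ISTC",
    "lateraloccipital": "LOCC",
    "lateralorbitofrontal": "LOF",
    "lingual": "LING",
    "medialorbitofrontal": "MOF",
    "middletemporal": "MTG",
    "parahippocampal": "PARH",
    "paracentral": "PARC",
    "parsopercularis": "POPE",
    "parsorbitalis": "PORB",
    "parstriangularis": "PTRI",
    "pericalcarine": "PCAL",
    "postcentral": "PSTC",
    "posteriorcingulate": "PCC",
    "precentral": "PREC",
    "precuneus": "PCUN",
    "rostralanteriorcingulate": "RACC",
    "rostralmiddlefrontal": "RMF",
    "superiorfrontal": "SFG",
    "superiorparietal": "SPL",
    "superiortemporal": "STG",
    "supramarginal": "SMAR",
    "frontalpole": "FP",
    "temporalpole": "TP",
    "transversetemporal": "TT",
    "insula": "INS",
}

#: 68 labels, left hemisphere (``.L``) regions 1-34, right (``.R``) 35-68.
DK68_LABELS: tuple[str, ...] = tuple(
    f"{_DK_ABBREV[name]}.{hemi}" for hemi in ("L", "R") for name in DK_REGIONS
)

#: 90 AAL labels in the canonical AAL numbering (odd = left, even = right).
AAL90_LABELS: tuple[str, ...] = (
    "PreCG.L", "PreCG.R",
    "SFGdor.L", "SFGdor.R",
    "ORBsup.L", "ORBsup.R",
    "MFG.L", "MFG.R",
    "ORBmid.L", "ORBmid.R",
    "IFGoperc.L", "IFGoperc.R",
    "IFGtriang.L", "IFGtriang.R",
    "ORBinf.L", "ORBinf.R",
    "ROL.L", "ROL.R",
    "SMA.L", "SMA.R",
    "OLF.L", "OLF.R",
    "SFGmed.L", "SFGmed.R",
    "ORBsupmed.L", "ORBsupmed.R",
    "REC.L", "REC.R",
    "INS.L", "INS.R",
    "ACG.L", "ACG.R",
    "DCG.L", "DCG.R",
    "PCG.L", "PCG.R",
    "HIP.L", "HIP.R",
    "PHG.L", "PHG.R",
    "AMYG.L", "AMYG.R",
    "CAL.L", "CAL.R",
    "CUN.L", "CUN.R",
    "LING.L", "LING.R",
    "SOG.L", "SOG.R",
    "MOG.L", "MOG.R",
    "IOG.L", "IOG.R",
    "FFG.L", "FFG.R",
    "PoCG.L", "PoCG.R",
    "SPG.L", "SPG.R",
    "IPL.L", "IPL.R",
    "SMG.L", "SMG.R",
    "ANG.L", "ANG.R",
    "PCUN.L", "PCUN.R",
    "PCL.L", "PCL.R",
    "CAU.L", "CAU.R",
    "PUT.L", "PUT.R",
    "PAL.L", "PAL.R",
    "THA.L", "THA.R",
    "HES.L", "HES.R",
    "STG.L", "STG.R",
    "TPOsup.L", "TPOsup.R",
    "MTG.L", "MTG.R",
    "TPOmid.L", "TPOmid.R",
    "ITG.L", "ITG.R",
)

N_DK = len(DK68_LABELS)
N_AAL = len(AAL90_LABELS)

assert N_DK == 68 and N_AAL == 90
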