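"""Controlled vocabularies shared across the pipeline."""

# Level-1 ChEMBL-style protein target classes used for the class
# distributions.  "membrane receptor" is broken out by its 7TM sub-class
# when a level-2 label is available.
LEVEL1_CLASSES = (
    "ion channel",
    "membrane receptor",
    "secreted",
    "structural",
    "surface antigen",
    "transcription factor",
    "transporter",
    "auxiliary transport protein",
    "enzyme",
    "enzyme modulator",
    "epigenetic regulator",
)

# Mammalian Phenotype index terms that define the neurophenotype score.
MP_NERVOUS_SYSTEM = "MP:0003631"
MP_BEHAVIOR_NEUROLOGICAL = "MP:0005386"
NEURO_INDEX_TERMS = frozenset({MP_NERVOUS_SYSTEM, MP_BEHAVIOR_NEUROLOGICAL})

# Background sizes for the target-development-level summary: human targets
# of approved drugs, and protein-coding genes in the genome.
DRUGGABLE_GENOME_SIZE = 667
TOTAL_GENOME_SIZE = 20120
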