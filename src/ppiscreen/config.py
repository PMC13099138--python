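"""Pinned numerical constants shared across the pipeline.

Everything here is a fixed convention of the method, collected in one
place so that reports can state exactly which constants produced them.
"""

# Interface definition: a residue is interfacial when its representative
# atom (C-beta, or C-alpha for glycine) lies within this distance of a
# representative atom on the other entity.
INTERFACE_CUTOFF = 12.0  # Angstrom

# PAE matrices emitted by current predictors saturate at this value; it also
# serves as the sentinel for PAE statistics of contact-free models.
PAE_MAX = 31.75  # Angstrom

# DockQ composite-score constants (interface-RMSD and ligand-RMSD scales)
# and the contact/interface distance definitions used by its components.
DOCKQ_IRMS_SCALE = 1.5   # Angstrom
DOCKQ_LRMS_SCALE = 8.5   # Angstrom
DOCKQ_CONTACT_CUTOFF = 5.0    # Angstrom, heavy-atom native contacts (Fnat)
DOCKQ_IFACE_CUTOFF = 10.0     # Angstrom, heavy-atom interface for iRMS
DOCKQ_ACCEPTABLE = 0.23       # "acceptable" model threshold (inclusive)

# Energy-term cutoffs and switching window.
LJ_CUTOFF = 6.0       # Angstrom
SOLV_CUTOFF = 6.0     # Angstrom
ELEC_CUTOFF = 10.0    # Angstrom (hard cutoff)
SWITCH_WIDTH = 0.5    # Angstrom, linear switch for LJ/solvation
COULOMB_CONSTANT = 332.0  # kcal*A/(mol*e^2)

# Backbone hydrogen-bond energy threshold (Kabsch-Sander style).
HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
HBOND_Q1Q2_FACTOR = 0.084 * 332.0

# pDockQ sigmoid constants from its original publication:
# pDockQ = L / (1 + exp(-k*(x - x0))) + b,
# x = mean interface pLDDT * log10(number of interface contacts).
PDOCKQ_L = 0.724
PDOCKQ_X0 = 152.611
PDOCKQ_K = 0.052
PDOCKQ_B = 0.018

# TM-score d0 floor.
TM_D0_FLOOR = 0.5  # Angstrom
TM_MIN_LENGTH = 15  # residues; d0 formula domain

# Default seed for splits, folds and training.
DEFAULT_SEED = 42

# Threshold grid for the operating-point table (screening report default).
DEFAULT_THRESHOLDS = (
    0.98, 0.95, 0.9, 0.85, 0.8, 0.75, 0.7, 0.64, 0.6, 0.56,
    0.5, 0.47, 0.4, 0.38, 0.28, 0.21, 0.18, 0.08, 0.05, 0.0,
)
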