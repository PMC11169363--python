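# Reference parameter file for the hemotwin trauma/hemorrhagic-shock model.
#
# All values are NON-CANONICAL defaults chosen so that (a) the model sits at
# an exact healthy steady state, (b) trajectories stay in physiologic ranges,
# and (c) the calibration machinery has a sensible starting point.  They are
# not fitted to any real cohort.  Units: time min, cytokines pg/mL, NO
# umol/L, volumes mL, pressure mmHg (mean arterial), platelets 10^3/uL,
# RBC relative mass (baseline 1), coagulation factors relative activity
# (healthy total = 1), cells arbitrary count units.
#
# Exactly 33 keys are fit-eligible (tagged global-fit or local-fit).

parameters:
  # --- inflammation core: baselines and turnover ---
  core.mo_baseline_blood:    {value: 500.0,  provenance: fixed-data}
  core.nu_baseline_blood:    {value: 4000.0, provenance: fixed-data}
  core.mo_baseline_lung:     {value: 100.0,  provenance: fixed-literature}
  core.nu_baseline_lung:     {value: 100.0,  provenance: fixed-literature}
  core.mo_baseline_tissue:   {value: 100.0,  provenance: fixed-literature}
  core.nu_baseline_tissue:   {value: 100.0,  provenance: fixed-literature}
  core.ecl_baseline:         {value: 1.0,    provenance: fixed-literature}
  core.ect_baseline:         {value: 1.0,    provenance: fixed-literature}
  core.d_cell:               {value: 0.01,   provenance: fixed-literature}
  core.d_cell_active:        {value: 0.05,   provenance: fixed-literature}
  core.d_ec_active:          {value: 0.02,   provenance: fixed-literature}

  # --- activation cascade ---
  core.k_act_mo:             {value: 0.05,   provenance: global-fit}
  core.k_act_nu:             {value: 0.05,   provenance: global-fit}
  core.k_act_ec:             {value: 0.05,   provenance: global-fit}
  core.k_act_scale:          {value: 1.0,    provenance: local-fit}
  core.k_act_pro:            {value: 1.0,    provenance: global-fit}
  core.x_act_pro:            {value: 100.0,  provenance: fixed-literature}
  core.k_act_coag:           {value: 0.5,    provenance: global-fit}
  core.x_act_coag:           {value: 0.3,    provenance: fixed-literature}
  core.x_act_anti:           {value: 50.0,   provenance: fixed-literature}
  core.k_mig_lung:           {value: 0.02,   provenance: global-fit}
  core.k_mig_tissue:         {value: 0.02,   provenance: global-fit}
  core.k_trauma_decay:       {value: 0.02,   provenance: local-fit}
  core.k_damp:               {value: 0.05,   provenance: fixed-literature}
  core.d_damp:               {value: 0.05,   provenance: fixed-literature}
  core.k_act_ect_damp:       {value: 0.5,    provenance: fixed-literature}
  core.x_damp:               {value: 10.0,   provenance: fixed-literature}

  # --- cytokines ---
  cyto.k_tnf:                {value: 0.3,    provenance: global-fit}
  cyto.k_il1:                {value: 0.1,    provenance: fixed-literature}
  cyto.k_il6:                {value: 0.15,   provenance: global-fit}
  cyto.k_il10:               {value: 0.08,   provenance: global-fit}
  cyto.k_il6_scale:          {value: 1.0,    provenance: local-fit}
  cyto.w_nu:                 {value: 0.3,    provenance: fixed-literature}
  cyto.w_ec:                 {value: 20.0,   provenance: fixed-literature}
  cyto.d_tnf:                {value: 0.10,   provenance: fixed-literature}
  cyto.d_il1:                {value: 0.07,   provenance: fixed-literature}
  cyto.d_il6:                {value: 0.04,   provenance: fixed-literature}
  cyto.d_il10:               {value: 0.04,   provenance: fixed-literature}

  # --- nitric oxide / iNOS ---
  no.K_no_ma:                {value: 0.01,   provenance: global-fit}
  no.K_no_ep:                {value: 0.2,    provenance: global-fit}
  no.K_no_inos:              {value: 0.05,   provenance: global-fit}
  no.K_bloodpressure_no:     {value: 0.5,    provenance: global-fit}
  no.k_inos_cells:           {value: 0.001,  provenance: fixed-literature}
  no.x_il10_inos:            {value: 50.0,   provenance: fixed-literature}
  no.d_inos:                 {value: 0.05,   provenance: fixed-literature}
  no.d_no:                   {value: 0.1,    provenance: fixed-literature}
  no.no_baseline:            {value: 10.0,   provenance: fixed-literature}

  # --- coagulation ---
  coag.platelets_baseline:   {value: 300.0,  provenance: fixed-data}
  coag.d_platelets:          {value: 0.002,  provenance: fixed-literature}
  coag.d_rbc:                {value: 0.001,  provenance: fixed-literature}
  coag.d_procoag_inactive:   {value: 0.002,  provenance: fixed-literature}
  coag.d_procoag_active:     {value: 0.05,   provenance: fixed-literature}
  coag.d_anticoag_inactive:  {value: 0.002,  provenance: fixed-literature}
  coag.d_anticoag_active:    {value: 0.05,   provenance: fixed-literature}
  coag.k_coag_trauma:        {value: 0.05,   provenance: global-fit}
  coag.k_coag_il6:           {value: 0.05,  provenance: global-fit}
  coag.x_coag_il6:           {value: 500.0,  provenance: fixed-literature}
  coag.k_coag_self:          {value: 0.05,   provenance: fixed-literature}
  coag.x_coag_self:          {value: 0.3,    provenance: fixed-literature}
  coag.x_anticoag:           {value: 0.5,    provenance: fixed-literature}
  coag.k_anti_act:           {value: 0.05,  provenance: fixed-literature}
  coag.k_clot:               {value: 0.004,  provenance: global-fit}
  coag.c_plt_consumption:    {value: 1.0,    provenance: fixed-literature}
  coag.c_procoag_consumption: {value: 0.1,   provenance: fixed-literature}
  coag.d_clot:               {value: 0.05,   provenance: fixed-literature}
  coag.k_fib_trauma:         {value: 2.0,    provenance: global-fit}
  coag.plasma_factor_conc:   {value: 1.0,    provenance: fixed-data}
  coag.rbc_product_conc:     {value: 2.0,    provenance: fixed-literature}
  coag.platelet_product_conc: {value: 1500.0, provenance: fixed-literature}

  # --- hemodynamics / oxygenation ---
  hemo.blood_volume_initial: {value: 2000.0, provenance: fixed-data}
  hemo.bp_baseline:          {value: 90.0,   provenance: fixed-data}
  hemo.k_bp_vol:             {value: 1.0,    provenance: fixed-literature}
  hemo.k_bp_sat:             {value: 0.5,    provenance: fixed-literature}
  hemo.k_vaso:               {value: 1.0,    provenance: fixed-literature}
  hemo.d_vaso:               {value: 0.1,    provenance: fixed-literature}
  hemo.k_bleed:              {value: 60.0,   provenance: local-fit}
  hemo.x_bleed_clot:         {value: 0.3,    provenance: fixed-literature}
  hemo.v_bleed_soft:         {value: 100.0,  provenance: fixed-literature}
  hemo.k_o2_epal:            {value: 0.3,    provenance: global-fit}
  hemo.vent_benefit:         {value: 1.0,    provenance: fixed-literature}

  # --- damage / death (fit globally on the human stage) ---
  damage.k_damage_bp:        {value: 1.5,    provenance: global-fit}
  damage.x_damage_bp:        {value: 15.0,   provenance: global-fit}
  damage.bp_damage_thresh:   {value: 65.0,   provenance: global-fit}
  damage.k_damage_o2sat:     {value: 1.0,    provenance: global-fit}
  damage.o2sat_damage_thresh: {value: 90.0,  provenance: global-fit}
  damage.k_damage_il6:       {value: 1.0,    provenance: global-fit}
  damage.x_damage_il6:       {value: 250.0,  provenance: global-fit}
  damage.il6_damage_thresh:  {value: 250.0,  provenance: global-fit}
  damage.k_damage_trauma:    {value: 1.0,    provenance: global-fit}
  death.death_threshold:     {value: 276.53, provenance: global-fit}

# Per-subject (local-fit) sampling ranges used by the synthetic cohorts and
# virtual populations.  Non-canonical stand-ins for fitted ranges.
local_ranges:
  core.k_act_scale:   [0.6, 1.6]
  core.k_trauma_decay: [0.01, 0.04]
  cyto.k_il6_scale:   [0.5, 2.0]
  hemo.k_bleed:       [30.0, 90.0]
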