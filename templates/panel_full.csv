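alias,parent,dims,method,sign,args
singlets,root,FSC-A|FSC-H,singlet,,band_k=4
live,singlets,LiveDead,mindensity,-,"gate_range=[-2,6];min_peak_height=0.01"
Tcell,live,CD3|CD19,quadrant,+-,
Bcell,live,CD3|CD19,quadrant,-+,
NK,live,CD16|CD56,quadrant,++,
mono,live,CD14|CD20,quadrant,+-,
lin_neg,live,,boolean,,expr=live&!Tcell&!Bcell&!NK&!mono
dc,lin_neg,CD14|HLA-DR,quadrant,-+,
CD4,Tcell,CD4|CD8,quadrant,+-,
CD8,Tcell,CD4|CD8,quadrant,-+,
tsub,Tcell,,kmeans_subsets,,"markers=CCR7,CD45RA,CD28;parents=CD4,CD8"
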