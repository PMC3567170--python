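pre,post,kind,contacts
ASEL,AIYL,chemical,6
ASEL,AIYR,chemical,2
ASER,AIYL,chemical,2
ASER,AIYR,chemical,8
AIYL,AIZL,chemical,6
AIYR,AIZR,chemical,6
AIYL,AIYR,gap,1
AIZL,AIZR,gap,2
AIZL,SMBDL,chemical,2
AIZL,SMBVL,chemical,3
AIZR,SMBDR,chemical,2
AIZR,SMBVR,chemical,3
SMBDL,SMBDL,chemical,1
SMBVL,SMBVL,chemical,1
SMBDR,SMBDR,chemical,1
SMBVR,SMBVR,chemical,1
ASEL,AIAL,chemical,1
AIAL,AIZL,chemical,1
ASER,RIAL,chemical,3
RIAL,RIBL,chemical,3
RIBL,RIML,chemical,3
RIML,SMBDL,chemical,3
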