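# EXAMPLE factor table with synthetic placeholder values — NOT literature values.
# Supply your own table (same columns) for real accounting work.
# key: stock (t C ha-1) | pristine/drained (t C ha-1 yr-1) | WTL code -3..2
# sign convention: positive = release to atmosphere, negative = net uptake
zone,wetland_type,key,value,units
*,marsh,stock,200,t C ha-1
*,mangrove,stock,350,t C ha-1
*,swamp,stock,300,t C ha-1
*,peatland,stock,600,t C ha-1
*,seasonal,stock,100,t C ha-1
*,marsh,pristine,-0.5,t C ha-1 yr-1
*,mangrove,pristine,-0.8,t C ha-1 yr-1
*,swamp,pristine,-0.4,t C ha-1 yr-1
*,peatland,pristine,-0.6,t C ha-1 yr-1
*,seasonal,pristine,-0.2,t C ha-1 yr-1
*,marsh,drained,2.0,t C ha-1 yr-1
*,mangrove,drained,3.5,t C ha-1 yr-1
*,swamp,drained,2.5,t C ha-1 yr-1
*,peatland,drained,5.0,t C ha-1 yr-1
*,seasonal,drained,1.0,t C ha-1 yr-1
*,*,-3,4.0,t CO2 ha-1 yr-1
*,*,-2,1.5,t CO2 ha-1 yr-1
*,*,-1,0.6,t CO2 ha-1 yr-1
*,*,0,0.1,t CO2 ha-1 yr-1
*,*,1,-1.2,t CO2 ha-1 yr-1
*,*,2,-0.3,t CO2 ha-1 yr-1
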